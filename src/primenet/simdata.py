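"""Synthetic pegRNA-target datasets with planted epigenetic structure.

The generator builds one synthetic chromosome, lays block-structured
accessibility (exponential peak/gap lengths, as DNase peaks look) and
Bernoulli CpG methylation over it, and draws 99-nt target windows with a
realistic region layout: a 20-nt protospacer, 3-nt PAM, a PBS of 8-17 nt
ending at the nick 3 nt upstream of the PAM, and an RT template of 10-30 nt
starting at the nick. The edit (substitution, small insertion or deletion)
lands inside the RT region.

Outcomes are planted through a latent valid-edit score

    s0 = b0 + b_acc * acc(protospacer|PAM) - b_meth * meth(protospacer|PAM)
         + b_gc * GC(PBS)

where acc/meth are accessible/methylated fractions of the protospacer+PAM
window. The noiseless expected triple is the 3-way logistic (softmax) map of
(s0, -s0, fixed erroneous logit) scaled to percent; the observed triple is a
Dirichlet draw around the same map of the noisy score s0 + eps, so triples
always sum to exactly 100. Every quantity used is stored as ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epitracks import IntervalSet
from .io_formats import EfficiencyTriple, GenomicAnchor, RegionSpans, TargetRecord

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset",
           "oracle_expected_triple", "make_fixture", "FIXTURES"]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PROTOSPACER_LEN = 20
PAM_LEN = 3
NICK_OFFSET = 17  # nick 3 nt upstream of the PAM, in protospacer coordinates


@dataclass(frozen=True)
class SimulationConfig:
    n_records: int = 1000
    seq_length: int = 99
    pbs_length_range: tuple = (8, 17)
    rt_length_range: tuple = (10, 30)
    # accessibility block model: exponential peak/gap lengths
    mean_block_length: float = 300.0
    coverage_fraction: float = 0.4
    # methylation model
    cpg_methylation_prob: float = 0.3
    minus_strand_fraction: float = 0.2
    # planted effects on the latent valid-edit score
    beta0: float = -1.5
    beta_acc: float = 2.0
    beta_meth: float = 1.0
    beta_gc: float = 1.0
    erroneous_logit: float = -1.0
    noise_scale: float = 0.25
    concentration: float = 200.0
    chrom_name: str = "chrS"

    def __post_init__(self):
        if self.seq_length > 128:
            raise ValueError("sequences cannot exceed the 128-nt frame")
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage fraction must be in [0, 1]")
        lo = self.pbs_length_range[0]
        hi = self.rt_length_range[1]
        if NICK_OFFSET + hi + 10 > self.seq_length or lo < 1:
            raise ValueError("region layout infeasible for this sequence length")


@dataclass
class GroundTruth:
    """Per-record planted quantities, keyed by record_id."""

    latent_noiseless: dict = field(default_factory=dict)
    latent_noisy: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)  # acc_frac, meth_frac, gc_pbs
    expected_triple: dict = field(default_factory=dict)
    planted_region: dict = field(default_factory=dict)  # proto|PAM span (wild coords)


def _softmax_triple(s: float, err_logit: float) -> np.ndarray:
    logits = np.array([s, -s, err_logit], dtype=float)
    e = np.exp(logits - logits.max())
    return 100.0 * e / e.sum()


def oracle_expected_triple(features: dict, config: SimulationConfig) -> EfficiencyTriple:
    """Closed-form noiseless expected triple for one record's planted features."""
    s0 = (config.beta0
          + config.beta_acc * features["acc_frac"]
          - config.beta_meth * features["meth_frac"]
          + config.beta_gc * features["gc_pbs"])
    t = _softmax_triple(s0, config.erroneous_logit)
    return EfficiencyTriple(*t)


def _simulate_blocks(rng, genome_len: int, mean_block: float,
                     coverage: float) -> list[tuple[int, int]]:
    """Alternating exponential peak/gap blocks hitting the target coverage."""
    if coverage <= 0:
        return []
    if coverage >= 1:
        return [(0, genome_len)]
    mean_gap = mean_block * (1.0 - coverage) / coverage
    intervals = []
    pos = int(rng.exponential(mean_gap))
    while pos < genome_len:
        length = max(1, int(rng.exponential(mean_block)))
        end = min(pos + length, genome_len)
        intervals.append((pos, end))
        pos = end + max(1, int(rng.exponential(mean_gap)))
    return intervals


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _apply_edit(rng, wild: str, rt_start: int, rt_end: int) -> str:
    """Random edit inside the RT region, downstream of the nick."""
    lo = rt_start + 1
    hi = min(rt_end - 1, rt_start + 10)
    e = int(rng.integers(lo, max(lo + 1, hi + 1)))
    kind = rng.random()
    if kind < 0.7:  # substitution
        alt = [b for b in "ACGT" if b != wild[e]]
        return wild[:e] + alt[int(rng.integers(3))] + wild[e + 1:]
    n = int(rng.integers(1, 3))
    if kind < 0.85:  # insertion
        ins = "".join(_BASES[rng.integers(0, 4, n)])
        return wild[:e] + ins + wild[e:]
    return wild[:e] + wild[e + n:]  # deletion


def simulate_dataset(config: SimulationConfig, seed: int):
    """Generate (records, dnase IntervalSet, methyl IntervalSet, GroundTruth)."""
    rng = np.random.default_rng(seed)
    L = config.seq_length
    genome_len = max(10_000, config.n_records * (L + 40))
    genome = "".join(_BASES[rng.integers(0, 4, genome_len)])

    dnase = IntervalSet.from_dict({
        config.chrom_name: _simulate_blocks(
            rng, genome_len, config.mean_block_length, config.coverage_fraction
        )
    })
    cpg = np.array([i for i in range(genome_len - 1)
                    if genome[i] == "C" and genome[i + 1] == "G"], dtype=np.int64)
    methylated = cpg[rng.random(len(cpg)) < config.cpg_methylation_prob]
    methyl = IntervalSet.from_dict({
        config.chrom_name: [(int(p), int(p) + 1) for p in methylated]
    })

    records: list[TargetRecord] = []
    truth = GroundTruth()
    pbs_lo, pbs_hi = config.pbs_length_range
    rt_lo, rt_hi = config.rt_length_range
    for i in range(config.n_records):
        rid = f"sim{i:06d}"
        start = int(rng.integers(0, genome_len - L))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        window = genome[start : start + L]
        wild = window if strand == "+" else _revcomp(window)

        pbs_len = int(rng.integers(pbs_lo, pbs_hi + 1))
        rt_len = int(rng.integers(rt_lo, rt_hi + 1))
        s_max = min(L - PROTOSPACER_LEN - PAM_LEN, L - NICK_OFFSET - rt_len)
        s = int(rng.integers(max(pbs_len - NICK_OFFSET, 0) + 2, s_max - 1))
        nick = s + NICK_OFFSET
        spans = RegionSpans(
            protospacer=(s, s + PROTOSPACER_LEN),
            pam=(s + PROTOSPACER_LEN, s + PROTOSPACER_LEN + PAM_LEN),
            pbs=(nick - pbs_len, nick),
            rt=(nick, nick + rt_len),
        )
        edited = _apply_edit(rng, wild, nick, nick + rt_len)
        anchor = GenomicAnchor(config.chrom_name, start, strand)

        # planted features over the protospacer+PAM window, wild orientation
        region = (s, s + PROTOSPACER_LEN + PAM_LEN)
        offsets = np.arange(region[0], region[1])
        genomic = (start + offsets if strand == "+"
                   else start + L - 1 - offsets)
        acc_frac = float(dnase.covers(config.chrom_name, genomic).mean())
        meth_frac = float(methyl.covers(config.chrom_name, genomic).mean())
        pbs_seq = wild[spans.pbs[0]: spans.pbs[1]]
        gc_pbs = (pbs_seq.count("G") + pbs_seq.count("C")) / len(pbs_seq)

        features = {"acc_frac": acc_frac, "meth_frac": meth_frac, "gc_pbs": gc_pbs}
        s0 = (config.beta0 + config.beta_acc * acc_frac
              - config.beta_meth * meth_frac + config.beta_gc * gc_pbs)
        s_noisy = s0 + rng.normal(0.0, config.noise_scale)
        expected = _softmax_triple(s0, config.erroneous_logit)
        p_noisy = _softmax_triple(s_noisy, config.erroneous_logit) / 100.0
        observed = rng.dirichlet(config.concentration * p_noisy) * 100.0

        records.append(TargetRecord(
            record_id=rid, wild_seq=wild, edited_seq=edited, spans=spans,
            anchor=anchor, observed=EfficiencyTriple(*observed),
            cell_line="sim",
        ))
        truth.latent_noiseless[rid] = s0
        truth.latent_noisy[rid] = s_noisy
        truth.features[rid] = features
        truth.expected_triple[rid] = EfficiencyTriple(*expected)
        truth.planted_region[rid] = region
    return records, dnase, methyl, truth


# The recovery fixture carries strong, cleanly recoverable planted effects
# (low latent noise, tight outcome dispersion) for end-to-end pipeline tests;
# tiny/smoke use the default, noisier conditions.
FIXTURES = {
    "tiny": dict(n_records=32, seed=7),
    "smoke": dict(n_records=300, seed=11),
    "recovery": dict(n_records=5000, seed=13, noise_scale=0.1,
                     concentration=1000.0),
}


def make_fixture(name: str, **overrides):
    """Deterministic canned datasets for tests and docs."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    spec = dict(FIXTURES[name])
    seed = spec.pop("seed")
    config = SimulationConfig(**{**spec, **overrides})
    return simulate_dataset(config, seed)
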