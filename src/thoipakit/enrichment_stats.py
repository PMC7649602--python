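"""Composition statistics of TM helix interfaces.

* Bootstrapped two-sample t-tests for comparing feature values between
  interface and non-interface residues without a normality assumption.
* Residue-class enrichment at interfaces: the proportion of a residue class
  at interfacial positions divided by its proportion across all TMD
  sequences (> 1 means the class is over-represented at interfaces).
* Motif abundance against composition-preserving nulls: each sequence is
  shuffled (same length, same amino-acid multiset) 100 times and motifs are
  re-counted; for interfacial-motif fractions the shuffled sequences are
  scored against the *fixed* interface masks, so the null captures what the
  mask geometry alone would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import errors
from .msa_features import motif_pair_positions

DEFAULT_N_RANDOM = 100


@dataclass
class EnrichmentResult:
    residue_class: str
    interface_fraction: float
    overall_fraction: float

    @property
    def ratio(self) -> float:
        return self.interface_fraction / self.overall_fraction


@dataclass
class MotifNull:
    """Composition-preserving randomisation summary for one motif statistic."""

    n_random: int
    seed: int
    per_replicate: np.ndarray  # statistic value in each randomised dataset
    mean: float


def bootstrap_ttest(a, b, n_boot: int = 10000, seed: int = 0) -> float:
    """Two-sample bootstrap p-value for a difference in means.

    The observed statistic is the equal-variance two-sample t; the null
    distribution resamples both groups (with replacement, original sizes)
    from the pooled, mean-centred data.  Returns
    ``p = (1 + #{|t*| >= |t_obs|}) / (n_boot + 1)``, so p is in (0, 1].
    Two identical constant samples are a defined degenerate case with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise errors.EmptyDataError("both samples must be non-empty")
    pooled_centred = np.concatenate([a - a.mean(), b - b.mean()])
    if np.allclose(pooled_centred.std(), 0):
        # both samples constant: equal means are the defined degenerate case
        return 1.0 if np.isclose(a.mean(), b.mean()) else 1.0 / (n_boot + 1)
    t_obs, _ = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t_obs):
        return 1.0
    rng = np.random.default_rng(seed)
    astar = rng.choice(pooled_centred, size=(n_boot, a.size), replace=True)
    bstar = rng.choice(pooled_centred, size=(n_boot, b.size), replace=True)
    tstar, _ = stats.ttest_ind(astar, bstar, axis=1, equal_var=True)
    tstar = np.nan_to_num(tstar)
    exceed = (np.abs(tstar) >= abs(t_obs)).sum()
    return float((1 + exceed) / (n_boot + 1))


def residue_enrichment(records, residue_class, class_name: str | None = None) -> EnrichmentResult:
    """Enrichment of a residue class at interfaces over a labelled TMD set.

    ``records`` are TMDRecords with interface masks; ``residue_class`` is a
    set of one-letter codes (e.g. {"G"} or the strongly-polar set).
    """
    members = frozenset(residue_class)
    name = class_name or "".join(sorted(members))
    n_total = n_class = n_iface = n_class_iface = 0
    for rec in records:
        if rec.interface_mask is None:
            raise errors.EmptyDataError(f"{rec.id}: interface mask required")
        for res, flag in zip(rec.sequence, rec.interface_mask):
            n_total += 1
            is_member = res in members
            n_class += is_member
            if flag:
                n_iface += 1
                n_class_iface += is_member
    if n_class == 0:
        raise errors.UndefinedMetricError(f"class {name!r} absent from the dataset")
    if n_iface == 0:
        raise errors.UndefinedMetricError("dataset has no interface residues")
    return EnrichmentResult(
        residue_class=name,
        interface_fraction=n_class_iface / n_iface,
        overall_fraction=n_class / n_total,
    )


def _shuffled(seq: str, rng) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def motif_abundance_with_null(
    sequences, members, n_random: int = DEFAULT_N_RANDOM, seed: int = 0
) -> tuple[int, MotifNull]:
    """Observed motif-instance count vs composition-preserving shuffle null.

    ``members`` defines the pair class at i,i+4 spacing (e.g. {"G"} for
    GxxxG).  Each replicate shuffles every sequence independently and counts
    instances over the whole dataset; the null mean is the average count.
    """
    members = frozenset(members)
    observed = sum(len(motif_pair_positions(s, members)) for s in sequences)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_random)
    for r in range(n_random):
        reps[r] = sum(
            len(motif_pair_positions(_shuffled(s, rng), members)) for s in sequences
        )
    return observed, MotifNull(n_random, seed, reps, float(reps.mean()))


def motif_interface_fraction(
    records, members, n_random: int = DEFAULT_N_RANDOM, seed: int = 0
) -> tuple[float, MotifNull]:
    """Percentage of motifs whose two defining residues are both interfacial.

    Observed: over all motif instances in the dataset, the percentage with
    both the i and i+4 residue on the interface.  Null: sequences are
    shuffled with composition preserved while the interface masks stay fixed
    to their positions; the same percentage is computed per replicate and
    averaged.  Values are percentages (0-100).
    """
    members = frozenset(members)
    for rec in records:
        if rec.interface_mask is None:
            raise errors.EmptyDataError(f"{rec.id}: interface mask required")

    def pct(seqs_masks) -> float:
        total = both = 0
        for seq, mask in seqs_masks:
            for i, j in motif_pair_positions(seq, members):
                total += 1
                both += bool(mask[i] and mask[j])
        if total == 0:
            return np.nan
        return 100.0 * both / total

    observed = pct((r.sequence, r.interface_mask) for r in records)
    if np.isnan(observed):
        raise errors.UndefinedMetricError("dataset contains no motif instance")
    rng = np.random.default_rng(seed)
    # shuffled replicates may lack the motif entirely; those are undefined
    # and excluded from the null mean
    reps = np.empty(n_random)
    for rep in range(n_random):
        reps[rep] = pct(
            (_shuffled(r.sequence, rng), r.interface_mask) for r in records
        )
    return observed, MotifNull(n_random, seed, reps, float(np.nanmean(reps)))
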