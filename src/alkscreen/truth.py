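"""Confirmatory-assay simulation and concordance evaluation.

Break-apart FISH is modeled as binomial sampling of scored tumor cells: each
of ``n_cells`` cells shows a rearranged signal pattern with probability
equal to the specimen's tumor fraction (or a small false-signal rate in
truly negative specimens).  The clinical rule calls a specimen positive when
strictly more than 15% of 50 scored cells are rearranged, i.e. at least 8
cells.  IHC is a 0-3 protein-staining score binarized at 2+, with the score
capped at 1 unless rearranged cells exceed 10% of the specimen.

Concordance compares PCR calls (index test) against FISH (reference):
sensitivity = P(PCR+ | FISH+), specificity = P(PCR- | FISH-), with
indeterminate PCR calls excluded from the 2x2 table and listed separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .caller import AlkCall
from .screen import ValidationError
from .synthetic import TruthRecord

__all__ = [
    "FISH_CELLS_DEFAULT",
    "FISH_THRESHOLD_DEFAULT",
    "FishResult",
    "IhcResult",
    "ConcordanceTable",
    "simulate_fish",
    "fish_positive_probability",
    "simulate_ihc",
    "concordance",
]

FISH_CELLS_DEFAULT = 50
FISH_THRESHOLD_DEFAULT = 0.15

# default IHC score distributions: degenerate (rule-like), overridable with
# a {status: [P(score 0..3)]} table
DEFAULT_IHC_DIST = {
    "positive": (0.0, 0.0, 0.0, 1.0),
    "negative": (1.0, 0.0, 0.0, 0.0),
}
IHC_FRACTION_FLOOR = 0.10  # staining must cover >10% of tumor cells


@dataclass(frozen=True)
class FishResult:
    sample_id: str
    cells_scored: int
    cells_positive: int
    call: str  # positive | negative


@dataclass(frozen=True)
class IhcResult:
    sample_id: str
    score: int  # 0..3
    call: str


@dataclass
class ConcordanceTable:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    discordant_ids: list[str] = field(default_factory=list)
    indeterminate_ids: list[str] = field(default_factory=list)


def fish_positive_probability(
    f: float,
    n_cells: int = FISH_CELLS_DEFAULT,
    threshold: float = FISH_THRESHOLD_DEFAULT,
) -> float:
    """Exact probability that binomial cell scoring calls a specimen
    positive: P(K > threshold * n_cells) with K ~ Binomial(n_cells, f)."""
    if not (0.0 <= f <= 1.0):
        raise ValidationError("cell-positivity probability must be in [0, 1]")
    return float(binom.sf(math.floor(threshold * n_cells), n_cells, f))


def simulate_fish(
    truth: TruthRecord,
    n_cells: int = FISH_CELLS_DEFAULT,
    threshold: float = FISH_THRESHOLD_DEFAULT,
    false_signal_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> FishResult:
    """Simulate break-apart FISH scoring of one specimen.

    Rearranged-pattern cells are Binomial(n_cells, f) with f the tumor
    fraction for true positives and ``false_signal_rate`` otherwise; the
    call is positive iff the count strictly exceeds ``threshold * n_cells``.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = truth.tumor_fraction if truth.true_status == "positive" else false_signal_rate
    k = int(rng.binomial(n_cells, f))
    call = "positive" if k > threshold * n_cells else "negative"
    return FishResult(truth.sample_id, n_cells, k, call)


def simulate_ihc(
    truth: TruthRecord,
    score_dist: dict[str, tuple[float, ...]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> IhcResult:
    """Simulate binary-scored ALK IHC.

    The 0-3 score is drawn from a categorical distribution conditional on
    true status; when rearranged cells do not exceed 10% of the specimen the
    score is capped at 1 (faint staining at most).  Call is positive iff the
    score is 2+ or 3+.
    """
    dist = DEFAULT_IHC_DIST if score_dist is None else score_dist
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = np.asarray(dist[truth.true_status], dtype=float)
    probs = probs / probs.sum()
    score = int(rng.choice(4, p=probs))
    if truth.true_status == "positive" and truth.tumor_fraction <= IHC_FRACTION_FLOOR:
        score = min(score, 1)
    call = "positive" if score >= 2 else "negative"
    return IhcResult(truth.sample_id, score, call)


def concordance(
    calls: list[AlkCall], reference: list[FishResult]
) -> ConcordanceTable:
    """2x2 agreement of PCR calls (index) against FISH calls (reference)."""
    ref = {r.sample_id: r.call for r in reference}
    idx = {c.sample_id: c.status for c in calls}
    if set(ref) != set(idx):
        raise ValidationError("sample ids of calls and reference differ")
    tp = fp = fn = tn = 0
    discordant: list[str] = []
    indeterminate: list[str] = []
    for sid in sorted(ref):
        pcr, fish = idx[sid], ref[sid]
        if pcr == "indeterminate":
            indeterminate.append(sid)
            continue
        if pcr == "positive" and fish == "positive":
            tp += 1
        elif pcr == "positive" and fish == "negative":
            fp += 1
            discordant.append(sid)
        elif pcr == "negative" and fish == "positive":
            fn += 1
            discordant.append(sid)
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return ConcordanceTable(tp, fp, fn, tn, sens, spec, discordant, indeterminate)
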