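"""Three-level qPCR ALK-rearrangement caller.

A sample is scored on three kinds of evidence derived from a cycle-threshold
(Ct) table:

1. marker ΔCt — Ct of the marker non-coding RNA assay minus the mean Ct of
   the HPRT1 and ESD reference genes (low values = high marker expression);
2. 5'/3' imbalance ΔCt — Ct(ALK 3') minus Ct(ALK 5'); fusions retain and
   overexpress the 3' kinase-domain side, so positives are negative here;
3. fusion-subtype panel — a variant-specific amplicon detected below a Ct
   threshold with the expected melt temperature identifies the fusion.

The combined score (marker ΔCt + imbalance ΔCt) is the primary classifier;
cutoffs are learned from labeled samples (perfect-separation midpoint, or
the Youden-J maximizer when classes overlap).  A detected subtype overrides
a score-negative call, with a discordance annotation — the mechanism by
which low-tumor-fraction specimens can be PCR-positive yet FISH-negative.

Censored (no-amplification) Ct values carry information (absence of the
fusion transcript) and are replaced by the max-cycle sentinel with an
explicit flag, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import ValidationError

__all__ = [
    "MARKER",
    "ALK5P",
    "ALK3P",
    "HPRT1",
    "ESD",
    "CORE_TARGETS",
    "MAX_CT_DEFAULT",
    "CT_DETECT_DEFAULT",
    "TM_TOL_DEFAULT",
    "QCError",
    "CtTable",
    "PanelPair",
    "PanelDef",
    "DeltaCt",
    "SubtypeCall",
    "AlkCall",
    "delta_ct_marker",
    "delta_ct_imbalance",
    "combined_score",
    "choose_cutoff",
    "derive_cutoffs",
    "call_subtype",
    "integrate_call",
    "call_cohort",
]

# canonical assay target ids
MARKER = "MARKER"  # the sweyjawbu-like non-coding RNA assay
ALK5P = "ALK5P"
ALK3P = "ALK3P"
HPRT1 = "HPRT1"
ESD = "ESD"
CORE_TARGETS = (MARKER, ALK5P, ALK3P, HPRT1, ESD)

MAX_CT_DEFAULT = 40.0  # cycles run per reaction; censoring ceiling
CT_DETECT_DEFAULT = 35.0  # panel amplicon must cross threshold by here
TM_TOL_DEFAULT = 0.5  # °C melt-peak window around the expected Tm


class QCError(ValueError):
    """A sample-level quality failure that prevents scoring."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _is_censored(ct) -> bool:
    return ct is None or (isinstance(ct, float) and np.isnan(ct))


@dataclass
class CtTable:
    """Long-format Ct table: one row per (sample, target).

    ``ct`` is NaN for censored (no-amplification) entries; ``tm`` is NaN
    where no melt temperature applies.
    """

    data: pd.DataFrame  # columns: sample_id, target_id, ct, tm
    max_ct: float = MAX_CT_DEFAULT

    def __post_init__(self) -> None:
        required = {"sample_id", "target_id", "ct", "tm"}
        if not required <= set(self.data.columns):
            raise ValidationError(f"CtTable needs columns {sorted(required)}")
        ct = self.data["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > self.max_ct))
        if bad.any():
            raise ValidationError(
                f"ct out of (0, {self.max_ct}] in rows {list(self.data.index[bad])}"
            )
        if self.data.duplicated(["sample_id", "target_id"]).any():
            raise ValidationError("duplicate (sample, target) entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    def sample_rows(self, sample_id: str) -> dict[str, tuple[float, float]]:
        """Map target -> (ct, tm) for one sample; censored ct is NaN."""
        sub = self.data[self.data["sample_id"] == sample_id]
        return {
            r.target_id: (float(r.ct) if pd.notna(r.ct) else float("nan"),
                          float(r.tm) if pd.notna(r.tm) else float("nan"))
            for r in sub.itertuples()
        }

    def get_ct(self, sample_id: str, target_id: str) -> float:
        """Ct for one entry; NaN if censored or absent."""
        sub = self.data[
            (self.data["sample_id"] == sample_id)
            & (self.data["target_id"] == target_id)
        ]
        if sub.empty:
            return float("nan")
        v = sub["ct"].iloc[0]
        return float(v) if pd.notna(v) else float("nan")


@dataclass(frozen=True)
class PanelPair:
    """One primer pair of the fusion-subtype panel."""

    pair_id: str
    variant_ids: tuple[str, ...]
    expected_tm: float

    def __post_init__(self) -> None:
        if not (70.0 < self.expected_tm < 95.0):
            raise ValidationError(
                f"pair {self.pair_id}: expected Tm {self.expected_tm} outside (70, 95) °C"
            )
        if len(self.variant_ids) == 0:
            raise ValidationError(f"pair {self.pair_id} covers no variant")


@dataclass
class PanelDef:
    """Fusion-subtype panel: primer pairs and the variants each covers."""

    pairs: list[PanelPair]

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pair ids in panel")

    @property
    def variants(self) -> set[str]:
        return {v for p in self.pairs for v in p.variant_ids}

    @property
    def partners(self) -> set[str]:
        return {v.split("-", 1)[0] for v in self.variants}

    def check_covers(self, variant_ids: Iterable[str]) -> None:
        missing = set(variant_ids) - self.variants
        if missing:
            raise ValidationError(
                f"variants covered by zero panel pairs: {sorted(missing)}"
            )


@dataclass(frozen=True)
class DeltaCt:
    """A ΔCt value plus a flag marking censored-sentinel arithmetic."""

    value: float
    censored: bool = False


@dataclass(frozen=True)
class SubtypeCall:
    """Result of panel interpretation for one sample."""

    variant: str | tuple[str, ...] | None
    multi_detection: bool = False
    ambiguous: bool = False

    @property
    def detected(self) -> bool:
        return self.variant is not None


@dataclass
class AlkCall:
    """Per-sample three-level evidence record."""

    sample_id: str
    dct_marker: float
    dct_imbalance: float
    combined: float
    status: str  # positive | negative | indeterminate
    variant_id: str | tuple[str, ...] | None
    evidence_flags: set[str] = field(default_factory=set)
    discordant: bool = False  # subtype-positive but score-negative
    qc_reason: str | None = None


# ---------------------------------------------------------------------------
# ΔCt arithmetic
# ---------------------------------------------------------------------------

def delta_ct_marker(
    ct_marker, ct_hprt1, ct_esd, max_ct: float = MAX_CT_DEFAULT
) -> DeltaCt:
    """Marker ΔCt: ct_marker - mean(ct_HPRT1, ct_ESD).

    A censored marker Ct is replaced by the max-cycle sentinel and flagged;
    a censored reference gene is a sample-level QC failure.
    """
    if _is_censored(ct_hprt1) or _is_censored(ct_esd):
        raise QCError("censored reference gene (HPRT1/ESD): no call possible")
    ref = (float(ct_hprt1) + float(ct_esd)) / 2.0
    if _is_censored(ct_marker):
        return DeltaCt(max_ct - ref, censored=True)
    return DeltaCt(float(ct_marker) - ref)


def delta_ct_imbalance(
    ct_alk3p, ct_alk5p, max_ct: float = MAX_CT_DEFAULT
) -> DeltaCt:
    """3'/5' imbalance ΔCt: ct(ALK 3') - ct(ALK 5').

    Negative when the 3' (kinase-domain) side is overexpressed, as in
    fusion-positive samples.  One censored side is replaced by the sentinel
    and flagged; both censored leaves the imbalance undefined (NaN, flagged).
    """
    c3, c5 = _is_censored(ct_alk3p), _is_censored(ct_alk5p)
    if c3 and c5:
        return DeltaCt(float("nan"), censored=True)
    v3 = max_ct if c3 else float(ct_alk3p)
    v5 = max_ct if c5 else float(ct_alk5p)
    return DeltaCt(v3 - v5, censored=c3 or c5)


def combined_score(dct_marker: float, dct_imbalance: float) -> float:
    """Sum of marker ΔCt and imbalance ΔCt (NaN propagates)."""
    return float(dct_marker) + float(dct_imbalance)


# ---------------------------------------------------------------------------
# cutoff learning
# ---------------------------------------------------------------------------

def choose_cutoff(scores, labels) -> float:
    """Choose a decision cutoff (score < cutoff ⇒ positive) from labeled data.

    When classes separate perfectly the cutoff is the midpoint between the
    maximum positive-class score and the minimum negative-class score.
    Otherwise the cutoff maximizing Youden's J = sensitivity + specificity
    − 1, with ties broken toward higher specificity (lower cutoff); a fully
    uninformative score (best J = 0) yields the median score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValidationError("cutoff needs both classes present")
    pos, neg = scores[labels], scores[~labels]
    if np.nanmax(pos) < np.nanmin(neg):
        return float((np.nanmax(pos) + np.nanmin(neg)) / 2.0)
    uniq = np.unique(scores[np.isfinite(scores)])
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        sens = float(np.mean(pos < c))
        spec = float(np.mean(neg >= c))
        j = sens + spec - 1.0
        key = (j, spec, -c)  # tie: higher specificity, then lower cutoff
        if best is None or key > best[0]:
            best = (key, c)
    if best[0][0] <= 0:
        return float(np.median(scores))
    return float(best[1])


def derive_cutoffs(
    dct_marker, dct_imbalance, combined, labels
) -> dict[str, float]:
    """Learn separate cutoffs for each evidence level from labeled samples."""
    return {
        "marker": choose_cutoff(dct_marker, labels),
        "imbalance": choose_cutoff(dct_imbalance, labels),
        "combined": choose_cutoff(combined, labels),
    }


# ---------------------------------------------------------------------------
# subtype panel interpretation
# ---------------------------------------------------------------------------

def call_subtype(
    sample_row: Mapping[str, tuple[float, float]],
    panel: PanelDef,
    ct_detect: float = CT_DETECT_DEFAULT,
    tm_tol: float = TM_TOL_DEFAULT,
) -> SubtypeCall:
    """Interpret the fusion-subtype panel for one sample.

    A pair is detected iff its amplicon Ct is at most ``ct_detect`` AND its
    melt temperature lies within ``tm_tol`` of the expected Tm.  Among
    detected pairs the one with lowest Ct wins (tie broken by lexicographic
    variant id), with a multi-detection flag when more than one pair fired.
    A winning pair covering several variants is ambiguous and returns the
    covering set.
    """
    detected: list[tuple[float, str, PanelPair]] = []
    for pair in panel.pairs:
        ct, tm = sample_row.get(pair.pair_id, (float("nan"), float("nan")))
        if np.isnan(ct) or ct > ct_detect:
            continue
        if np.isnan(tm) or abs(tm - pair.expected_tm) > tm_tol:
            continue
        detected.append((ct, min(pair.variant_ids), pair))
    if not detected:
        return SubtypeCall(None)
    detected.sort(key=lambda t: (t[0], t[1]))
    winner = detected[0][2]
    multi = len(detected) > 1
    if len(winner.variant_ids) > 1:
        return SubtypeCall(
            tuple(sorted(winner.variant_ids)), multi_detection=multi, ambiguous=True
        )
    return SubtypeCall(winner.variant_ids[0], multi_detection=multi)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_call(
    sample_id: str,
    dct_marker: DeltaCt,
    dct_imbalance: DeltaCt,
    cutoffs: Mapping[str, float],
    subtype: SubtypeCall,
) -> AlkCall:
    """Combine the three evidence levels into one status call.

    Evidence flags fire independently (each ΔCt below its own cutoff, and a
    detected subtype).  Status is positive when the combined score is below
    its cutoff or a subtype was detected; a subtype detected in a
    score-negative sample still yields a positive call, annotated as
    discordant — the signature of a specimen with very few
    rearrangement-bearing cells.
    """
    combined = combined_score(dct_marker.value, dct_imbalance.value)
    flags: set[str] = set()
    if np.isfinite(dct_marker.value) and dct_marker.value < cutoffs["marker"]:
        flags.add("marker")
    if np.isfinite(dct_imbalance.value) and dct_imbalance.value < cutoffs["imbalance"]:
        flags.add("imbalance")
    if subtype.detected:
        flags.add("subtype")
    score_positive = np.isfinite(combined) and combined < cutoffs["combined"]
    if score_positive:
        flags.add("combined")
    if score_positive or subtype.detected:
        status = "positive"
    elif np.isfinite(combined):
        status = "negative"
    else:
        status = "indeterminate"
    discordant = subtype.detected and not score_positive and np.isfinite(combined)
    return AlkCall(
        sample_id=sample_id,
        dct_marker=dct_marker.value,
        dct_imbalance=dct_imbalance.value,
        combined=combined,
        status=status,
        variant_id=subtype.variant,
        evidence_flags=flags,
        discordant=discordant,
    )


def _sample_metrics(
    table: CtTable, sample_id: str
) -> tuple[DeltaCt, DeltaCt, dict[str, tuple[float, float]]]:
    row = table.sample_rows(sample_id)
    for ref in (HPRT1, ESD):
        if ref not in row:
            raise QCError(
                f"sample {sample_id}: reference gene {ref} missing; "
                "HPRT1 and ESD Cts are required for normalization"
            )
    m = delta_ct_marker(
        row.get(MARKER, (float("nan"), float("nan")))[0],
        row[HPRT1][0],
        row[ESD][0],
        max_ct=table.max_ct,
    )
    imb = delta_ct_imbalance(
        row.get(ALK3P, (float("nan"), float("nan")))[0],
        row.get(ALK5P, (float("nan"), float("nan")))[0],
        max_ct=table.max_ct,
    )
    return m, imb, row


def call_cohort(
    table: CtTable,
    panel: PanelDef,
    cutoffs: Mapping[str, float] | None = None,
    training_labels: Mapping[str, bool] | None = None,
    ct_detect: float = CT_DETECT_DEFAULT,
    tm_tol: float = TM_TOL_DEFAULT,
) -> tuple[list[AlkCall], dict[str, float]]:
    """Call ALK status for every sample in a Ct table.

    Cutoffs are either supplied or learned from ``training_labels``
    (sample_id -> true positive?).  Samples failing reference-gene QC are
    reported as indeterminate with the reason.  Returns the calls and the
    cutoffs used.
    """
    metrics: dict[str, tuple[DeltaCt, DeltaCt, dict]] = {}
    qc_failed: dict[str, str] = {}
    for sid in table.sample_ids:
        try:
            metrics[sid] = _sample_metrics(table, sid)
        except QCError as e:
            qc_failed[sid] = str(e)

    if cutoffs is None:
        if training_labels is None:
            raise ValidationError("need either cutoffs or training labels")
        sids = [s for s in metrics if s in training_labels]
        labels = [bool(training_labels[s]) for s in sids]
        dm = [metrics[s][0].value for s in sids]
        di = [metrics[s][1].value for s in sids]
        cb = [combined_score(metrics[s][0].value, metrics[s][1].value) for s in sids]
        cutoffs = derive_cutoffs(dm, di, cb, labels)

    calls: list[AlkCall] = []
    for sid in table.sample_ids:
        if sid in qc_failed:
            calls.append(
                AlkCall(
                    sample_id=sid,
                    dct_marker=float("nan"),
                    dct_imbalance=float("nan"),
                    combined=float("nan"),
                    status="indeterminate",
                    variant_id=None,
                    qc_reason=qc_failed[sid],
                )
            )
            continue
        m, imb, row = metrics[sid]
        subtype = call_subtype(row, panel, ct_detect=ct_detect, tm_tol=tm_tol)
        calls.append(integrate_call(sid, m, imb, cutoffs, subtype))
    return calls, dict(cutoffs)
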