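"""Microarray marker-discovery computations.

The screening stage mirrors the standard RMA-style preprocessing of
Affymetrix probe-level data (quantile normalization across arrays followed
by Tukey median-polish summarization of each probe set) and then scores
probe sets for differential expression between a positive class (e.g.
ALK-rearranged tumors) and everything else with the SAM moderated
d-statistic and permutation-based q-values.  Linear fold changes are
computed on the log2 scale and exponentiated, the convention for RMA
output.  A small ungapped Hamming-distance search maps short oligo probe
sequences onto transcript sequences, allowing a bounded number of
mismatches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ProbeMatrix",
    "ExpressionMatrix",
    "ProbeHit",
    "ValidationError",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "sam_two_class",
    "fold_change",
    "pearson_correlation",
    "match_probe",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe-level log2 intensities with probe->probe-set map and labels.

    Parameters
    ----------
    values : DataFrame
        Probes x samples, indexed by probe id.
    probeset_of : Series
        Maps each probe id to exactly one probe-set id.
    sample_labels : Series
        Subgroup tag per sample (index = sample id, aligned with columns).
    """

    values: pd.DataFrame
    probeset_of: pd.Series
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValidationError("probe intensities must be finite")
        if set(self.values.index) != set(self.probeset_of.index):
            raise ValidationError("probe ids of matrix and probe-set map differ")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids")
        if list(self.values.columns) != list(self.sample_labels.index):
            raise ValidationError("sample ids of matrix and labels differ")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Probe-set x sample log2 expression after summarization."""

    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValidationError("expression values must be finite")
        if list(self.values.columns) != list(self.sample_labels.index):
            raise ValidationError("sample ids of matrix and labels differ")


@dataclass(frozen=True)
class ProbeHit:
    """An ungapped placement of a probe on a transcript."""

    probe_id: str
    transcript_id: str
    start: int  # 0-based offset into the transcript (forward coordinates)
    strand: str  # '+' probe as given, '-' reverse complement
    mismatches: int


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values):
    """Quantile-normalize columns so each shares the mean empirical
    distribution.

    After normalization the sorted values of every column equal the
    across-column mean of sorted values; tied values within a column receive
    the mean of the reference values at their tied ranks.  Accepts an array
    or DataFrame and returns the same type.
    """
    is_frame = isinstance(values, pd.DataFrame)
    X = np.asarray(values, dtype=float)
    if X.size == 0:
        raise ValidationError("empty matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in input")
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        res = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            res[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = res
    if is_frame:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def median_polish(X, tol: float = 1e-10, max_iter: int = 100):
    """Tukey median polish of a 2-D array.

    Alternating row/column median sweeps until the largest absolute change
    of any effect in a full sweep falls below ``tol`` (or ``max_iter``).

    Returns
    -------
    (overall, row_effects, col_effects, residuals)
        with ``overall + row[i] + col[j] + residuals[i, j] == X[i, j]``.
    """
    Z = np.asarray(X, dtype=float).copy()
    if Z.ndim != 2 or Z.size == 0:
        raise ValidationError("median polish needs a nonempty 2-D matrix")
    n, m = Z.shape
    overall = 0.0
    row = np.zeros(n)
    col = np.zeros(m)
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.median(Z, axis=1)
        Z -= rmed[:, None]
        row += rmed
        delta = max(delta, np.abs(rmed).max())
        cshift = np.median(col)
        overall += cshift
        col -= cshift
        delta = max(delta, abs(cshift))
        cmed = np.median(Z, axis=0)
        Z -= cmed[None, :]
        col += cmed
        delta = max(delta, np.abs(cmed).max())
        rshift = np.median(row)
        overall += rshift
        row -= rshift
        delta = max(delta, abs(rshift))
        if delta < tol:
            break
    return overall, row, col, Z


def median_polish_summarize(
    matrix: ProbeMatrix, tol: float = 1e-10, max_iter: int = 100
) -> ExpressionMatrix:
    """Summarize each probe set to one expression value per sample.

    Per probe set, the probe x sample sub-matrix is decomposed by median
    polish; reported expression is overall effect + sample (column) effect,
    the RMA summarization convention.
    """
    groups = matrix.probeset_of.groupby(matrix.probeset_of).groups
    probeset_ids = sorted(groups)
    rows = np.empty((len(probeset_ids), matrix.n_samples))
    for i, ps in enumerate(probeset_ids):
        sub = matrix.values.loc[list(groups[ps])].to_numpy(float)
        if sub.shape[0] == 0:
            raise ValidationError(f"probe set {ps!r} has zero probes")
        overall, _, colfx, _ = median_polish(sub, tol=tol, max_iter=max_iter)
        rows[i] = overall + colfx
    values = pd.DataFrame(rows, index=probeset_ids, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, sample_labels=matrix.sample_labels)


# ---------------------------------------------------------------------------
# SAM two-class statistics
# ---------------------------------------------------------------------------

def _sam_r_s(X: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative difference numerator r_i and pooled standard error s_i."""
    n1 = int(pos.sum())
    n2 = int((~pos).sum())
    x1 = X[:, pos]
    x2 = X[:, ~pos]
    r = x1.mean(axis=1) - x2.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return r, s


def _choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 10) -> float:
    """SAM percentile rule: among candidate s0 values on the percentile grid
    of s, minimize the coefficient of variation of median |d| across windows
    of genes ordered by s."""
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="mergesort")
    k = min(n_windows, len(s))
    windows = np.array_split(order, k)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = r / (s + s0)
        meds = np.array([np.median(np.abs(d[w])) for w in windows])
        mu = meds.mean()
        if mu == 0:
            cv = 0.0 if np.allclose(meds, 0) else np.inf
        else:
            cv = meds.std() / mu
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _permutation_masks(
    n: int, n_pos: int, n_perm: int, seed: int
) -> np.ndarray:
    """Distinct class-assignment masks: exhaustive when the number of
    distinct label splits is at most n_perm, otherwise sampled without
    replacement."""
    from math import comb

    total = comb(n, n_pos)
    if total <= n_perm:
        combos = itertools.combinations(range(n), n_pos)
        masks = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combos):
            masks[b, list(idx)] = True
        return masks
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    masks = np.zeros((n_perm, n), dtype=bool)
    b = 0
    while b < n_perm:
        idx = tuple(sorted(rng.choice(n, size=n_pos, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        masks[b, list(idx)] = True
        b += 1
    return masks


def sam_two_class(
    expr: ExpressionMatrix,
    positive_label: str,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """SAM two-class differential expression with permutation q-values.

    d_i = (mean_pos - mean_rest) / (s_i + s0) with s_i the pooled two-sample
    standard-error term and s0 the fudge factor from the percentile rule.
    q-values are the median count, over label permutations, of permuted |d|
    values at or above each observed |d|, divided by the observed count at
    that threshold, clipped to [0, 1] and made monotone in the |d| ranking.

    Returns a DataFrame indexed by probeset_id with columns
    d_stat, s0, fold_change_linear, q_value, rank.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pos = (expr.sample_labels == positive_label).to_numpy()
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValidationError("both classes must be nonempty")
    X = expr.values.to_numpy(float)
    ids = np.asarray(expr.values.index, dtype=object)

    r, s = _sam_r_s(X, pos)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d = r / (s + s0)
    absd = np.abs(d)

    masks = _permutation_masks(len(pos), int(pos.sum()), n_perm, seed)
    perm_absd = np.empty((masks.shape[0], len(d)))
    for b in range(masks.shape[0]):
        rb, sb = _sam_r_s(X, masks[b])
        perm_absd[b] = np.abs(rb / (sb + s0))

    # rank 1..n by |d| descending, ties broken by probeset id
    order = np.lexsort((ids, -absd))
    rank = np.empty(len(d), dtype=int)
    rank[order] = np.arange(1, len(d) + 1)

    # observed count at each gene's threshold counts all ties
    obs_count = np.array([(absd >= a).sum() for a in absd])
    med_false = np.array(
        [np.median((perm_absd >= a).sum(axis=1)) for a in absd], dtype=float
    )
    q = np.clip(med_false / obs_count, 0.0, 1.0)

    # enforce monotonicity: q non-decreasing as |d| decreases
    q_ord = q[order]
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_ord

    fc = fold_change(expr, positive_label).to_numpy()
    out = pd.DataFrame(
        {
            "d_stat": d,
            "s0": s0,
            "fold_change_linear": fc,
            "q_value": q_mono,
            "rank": rank,
        },
        index=pd.Index(ids, name="probeset_id"),
    )
    return out.sort_values("rank")


def fold_change(expr: ExpressionMatrix, positive_label: str) -> pd.Series:
    """Linear fold change: 2**(mean log2 in positive class - mean log2 in
    the rest), per probe set."""
    pos = (expr.sample_labels == positive_label).to_numpy()
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValidationError("both classes must be nonempty")
    X = expr.values.to_numpy(float)
    diff = X[:, pos].mean(axis=1) - X[:, ~pos].mean(axis=1)
    return pd.Series(2.0 ** diff, index=expr.values.index, name="fold_change")


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; rejects degenerate (zero-variance) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("need two equal-length series of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# probe-to-transcript matching
# ---------------------------------------------------------------------------

_VALID_BASES = frozenset(b"ACGTN")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _encode(seq: str, what: str) -> np.ndarray:
    raw = seq.upper().encode()
    if not set(raw) <= _VALID_BASES:
        bad = sorted(set(raw) - _VALID_BASES)
        raise ValidationError(
            f"invalid characters in {what}: {bytes(bad).decode()!r}"
        )
    return np.frombuffer(raw, dtype=np.uint8)


def _hamming_hits(probe: np.ndarray, transcript: np.ndarray, max_mm: int):
    """Mismatch count at every ungapped offset. N never matches anything,
    so an N/N position also counts as a mismatch."""
    L, k = len(transcript), len(probe)
    if k > L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = sliding_window_view(transcript, k)
    mm = (windows != probe).sum(axis=1)
    n_byte = ord("N")
    probe_n = probe == n_byte
    if probe_n.any():
        # N facing N compares equal bytewise but must still count
        mm = mm + (windows[:, probe_n] == n_byte).sum(axis=1)
    starts = np.nonzero(mm <= max_mm)[0]
    return starts, mm[starts]


def match_probe(
    probe_seq: str,
    transcripts,
    max_mismatch: int = 1,
    search_reverse_complement: bool = True,
    probe_id: str = "probe",
) -> list[ProbeHit]:
    """Report every ungapped placement of the probe (and optionally its
    reverse complement) on each transcript with Hamming distance at most
    ``max_mismatch``, in forward transcript coordinates, sorted by
    (transcript, start, strand).

    ``transcripts`` is an iterable of ``(id, sequence)`` pairs or objects
    with ``.id`` and ``.seq`` (e.g. Bio.SeqRecord).
    """
    if len(probe_seq) < 1:
        raise ValidationError("empty probe sequence")
    p_fwd = _encode(probe_seq, "probe")
    p_rev = np.frombuffer(
        bytes(p_fwd)[::-1].translate(_COMPLEMENT), dtype=np.uint8
    )
    hits: list[ProbeHit] = []
    for rec in transcripts:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            tid, tseq = rec.id, str(rec.seq)
        else:
            tid, tseq = rec
        t = _encode(tseq, f"transcript {tid!r}")
        for strand, p in (("+", p_fwd), ("-", p_rev)):
            if strand == "-" and not search_reverse_complement:
                continue
            starts, mms = _hamming_hits(p, t, max_mismatch)
            hits.extend(
                ProbeHit(probe_id, tid, int(st), strand, int(mm))
                for st, mm in zip(starts, mms)
            )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.strand))
    return hits
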