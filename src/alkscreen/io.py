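"""Readers and writers for the pipeline's file formats.

Probe matrices travel as TSV (rows = probes; first columns probe_id and
probeset_id, remaining columns = samples), Ct data as long-format CSV with
the literal token NA for censored cycle thresholds, truth records as CSV,
fusion panels as TSV, call reports as JSON plus a flat CSV summary, and run
configuration as YAML.  All readers validate and raise parse errors that
name the file and offending line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .caller import AlkCall, CtTable, PanelDef, PanelPair
from .screen import ProbeHit, ProbeMatrix, ValidationError
from .synthetic import SimConfig, TruthRecord
from .truth import ConcordanceTable

__all__ = [
    "ParseError",
    "read_probe_matrix",
    "write_probe_matrix",
    "read_ct_table",
    "write_ct_table",
    "read_truth",
    "write_truth",
    "read_panel",
    "write_panel",
    "read_fasta",
    "write_de_results",
    "write_probe_hits",
    "write_calls",
    "read_calls",
    "write_concordance",
    "load_config",
    "save_config",
]


class ParseError(ValueError):
    """A malformed input file; the message names file and line."""


def _fail(path, line: int | None, msg: str):
    loc = f"{path}" if line is None else f"{path}, line {line}"
    raise ParseError(f"{loc}: {msg}")


# ---------------------------------------------------------------------------
# probe matrix (TSV) + truth (CSV, carries the sample labels)
# ---------------------------------------------------------------------------

def write_probe_matrix(matrix: ProbeMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "probeset_id", matrix.probeset_of.loc[out.index])
    out.insert(0, "probe_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_probe_matrix(path, labels: pd.Series | None = None) -> ProbeMatrix:
    """Read a probe-matrix TSV.  ``labels`` maps sample id -> subgroup tag
    (typically from the truth CSV); samples without a label get the empty
    tag."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "probeset_id": str})
    except Exception as e:  # noqa: BLE001 - re-raise with location
        _fail(path, None, f"unreadable TSV ({e})")
    for col in ("probe_id", "probeset_id"):
        if col not in df.columns:
            _fail(path, 1, f"missing required column {col!r}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        line = int(df.index[df["probe_id"] == dup][1]) + 2
        _fail(path, line, f"duplicate probe id {dup!r}")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "probeset_id")]
    if not sample_cols:
        _fail(path, 1, "no sample columns")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        _fail(path, int(np.flatnonzero(bad)[0]) + 2, "non-numeric intensity cell")
    values.index = df["probe_id"]
    probeset_of = pd.Series(
        df["probeset_id"].to_numpy(), index=df["probe_id"], name="probeset_id"
    )
    if labels is None:
        labels = pd.Series("", index=sample_cols, name="group_label")
    else:
        labels = labels.reindex(sample_cols).fillna("")
    return ProbeMatrix(values=values, probeset_of=probeset_of, sample_labels=labels)


def write_truth(records: list[TruthRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "true_status": t.true_status,
                "variant_id": t.variant_id or "",
                "tumor_fraction": t.tumor_fraction,
                "group_label": t.group_label,
            }
            for t in records
        ]
    ).to_csv(path, index=False)


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"sample_id", "true_status", "variant_id", "tumor_fraction", "group_label"}
    if not needed <= set(df.columns):
        _fail(path, 1, f"missing columns {sorted(needed - set(df.columns))}")
    records = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            records.append(
                TruthRecord(
                    sample_id=r.sample_id,
                    true_status=r.true_status,
                    variant_id=r.variant_id or None,
                    tumor_fraction=float(r.tumor_fraction),
                    group_label=r.group_label,
                )
            )
        except ValueError as e:
            _fail(path, i, str(e))
    return records


def truth_labels(records: list[TruthRecord]) -> pd.Series:
    return pd.Series(
        {t.sample_id: t.group_label for t in records}, name="group_label"
    )


# ---------------------------------------------------------------------------
# Ct table (CSV, NA = censored)
# ---------------------------------------------------------------------------

def write_ct_table(table: CtTable, path) -> None:
    out = table.data.copy()
    out["ct"] = out["ct"].map(lambda v: "NA" if pd.isna(v) else f"{v:.4f}")
    out["tm"] = out["tm"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out.to_csv(path, index=False)


def read_ct_table(path, max_ct: float = 40.0) -> CtTable:
    df = pd.read_csv(
        path, dtype={"sample_id": str, "target_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    needed = {"sample_id", "target_id", "ct"}
    if not needed <= set(df.columns):
        _fail(path, 1, f"missing columns {sorted(needed - set(df.columns))}")
    if "tm" not in df.columns:
        df["tm"] = np.nan
    for col in ("ct", "tm"):
        raw = df[col]
        num = pd.to_numeric(raw.mask(raw.astype(str).str.strip() == ""), errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            _fail(path, int(np.flatnonzero(bad)[0]) + 2,
                  f"non-numeric {col} cell {raw[bad].iloc[0]!r}")
        df[col] = num
    try:
        return CtTable(df[["sample_id", "target_id", "ct", "tm"]], max_ct=max_ct)
    except ValidationError as e:
        _fail(path, None, str(e))


# ---------------------------------------------------------------------------
# fusion panel (TSV)
# ---------------------------------------------------------------------------

def write_panel(panel: PanelDef, path) -> None:
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "variant_ids": ",".join(p.variant_ids),
                "expected_tm": p.expected_tm,
            }
            for p in panel.pairs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path, require_variants=None) -> PanelDef:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"pair_id", "variant_ids", "expected_tm"}
    if not needed <= set(df.columns):
        _fail(path, 1, f"missing columns {sorted(needed - set(df.columns))}")
    pairs = []
    for i, r in enumerate(df.itertuples(), start=2):
        variants = tuple(v for v in r.variant_ids.split(",") if v)
        try:
            pairs.append(PanelPair(r.pair_id, variants, float(r.expected_tm)))
        except ValueError as e:
            _fail(path, i, str(e))
    panel = PanelDef(pairs)
    if require_variants is not None:
        panel.check_covers(require_variants)
    return panel


def read_fasta(path):
    """Sequence records (Bio.SeqRecord) from a FASTA file."""
    return list(SeqIO.parse(str(path), "fasta"))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_de_results(de: pd.DataFrame, path) -> None:
    de.reset_index().to_csv(
        path, sep="\t", index=False,
        columns=["probeset_id", "d_stat", "fold_change_linear", "q_value", "rank"],
    )


def write_probe_hits(hits: list[ProbeHit], probe_lengths: dict[str, int], path) -> None:
    """BED-like TSV: transcript, start, end (half-open), probe, mismatches,
    strand."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.start + probe_lengths[h.probe_id]
            fh.write(
                f"{h.transcript_id}\t{h.start}\t{end}\t{h.probe_id}\t"
                f"{h.mismatches}\t{h.strand}\n"
            )


def _call_to_dict(c: AlkCall) -> dict:
    d = dataclasses.asdict(c)
    d["evidence_flags"] = sorted(c.evidence_flags)
    if isinstance(c.variant_id, tuple):
        d["variant_id"] = list(c.variant_id)
    for k in ("dct_marker", "dct_imbalance", "combined"):
        d[k] = None if not np.isfinite(d[k]) else d[k]
    return d


def write_calls(calls: list[AlkCall], cutoffs: dict, path_json, path_csv=None) -> None:
    payload = {
        "cutoffs": cutoffs,
        "calls": [_call_to_dict(c) for c in calls],
    }
    Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")
    if path_csv is not None:
        pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "dct_marker": c.dct_marker,
                    "dct_imbalance": c.dct_imbalance,
                    "combined": c.combined,
                    "status": c.status,
                    "variant_id": "|".join(c.variant_id)
                    if isinstance(c.variant_id, tuple)
                    else (c.variant_id or ""),
                    "evidence_flags": "|".join(sorted(c.evidence_flags)),
                    "discordant": c.discordant,
                }
                for c in calls
            ]
        ).to_csv(path_csv, index=False)


def read_calls(path_json) -> tuple[list[AlkCall], dict]:
    payload = json.loads(Path(path_json).read_text())
    calls = []
    for d in payload["calls"]:
        nan = float("nan")
        calls.append(
            AlkCall(
                sample_id=d["sample_id"],
                dct_marker=nan if d["dct_marker"] is None else d["dct_marker"],
                dct_imbalance=nan if d["dct_imbalance"] is None else d["dct_imbalance"],
                combined=nan if d["combined"] is None else d["combined"],
                status=d["status"],
                variant_id=tuple(d["variant_id"])
                if isinstance(d["variant_id"], list)
                else d["variant_id"],
                evidence_flags=set(d["evidence_flags"]),
                discordant=d.get("discordant", False),
                qc_reason=d.get("qc_reason"),
            )
        )
    return calls, payload.get("cutoffs", {})


def write_concordance(table: ConcordanceTable, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(table), indent=2) + "\n")


# ---------------------------------------------------------------------------
# run configuration (YAML)
# ---------------------------------------------------------------------------

def save_config(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["tumor_fraction_range"] = list(config.tumor_fraction_range)
    d["variant_catalogue"] = list(config.variant_catalogue)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        _fail(path, None, f"unknown config keys {sorted(unknown)}")
    if "tumor_fraction_range" in raw:
        raw["tumor_fraction_range"] = tuple(raw["tumor_fraction_range"])
    if "variant_catalogue" in raw:
        raw["variant_catalogue"] = tuple(raw["variant_catalogue"])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg
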