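"""Rare-variant filter cascade for annotated WES variant tables.

The cascade retains a variant iff

* its ExAC minor allele frequency is absent or below 3% for genes on the
  LGMD panel (1% for other genes), and
* at least one of the configured pathogenicity predictors (Mutation Taster,
  PolyPhen2, PROVEAN, SIFT by default) calls it damaging.

dbscSNV splice flagging is separate: a record is flagged iff *both* the
adaptive-boosting (ada) and random-forest (rf) scores are present and
strictly above 0.6.  ACMG evidence codes pass through as labels; nothing is
computed from them.  Ranking is a transparent deterministic stand-in for
phenotype-driven prioritizers: truncating variants first, then
splice-flagged ones, then missense by damaging-predictor count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_PREDICTORS = ("mutation_taster", "polyphen2", "provean", "sift")
DEFAULT_LGMD_PANEL = frozenset({
    "ANO5", "CAPN3", "DYSF", "SGCA", "SGCB", "SGCD", "SGCG", "TCAP",
    "TRIM32", "FKRP", "TTN", "POMT1", "POMT2", "FKTN", "POMGNT1",
    "DAG1", "PLEC", "DES", "TNPO3", "TRAPPC11", "GMPPB", "ISPD",
    "GAA", "LMNA", "MYOT", "CAV3", "DNAJB6", "HNRNPDL",
})
DBSCSNV_THRESHOLD = 0.6

DAMAGING_KEYWORDS = ("damaging", "deleterious", "disease")
BENIGN_KEYWORDS = ("benign", "tolerated", "neutral", "polymorphism")

TRUNCATING_TYPES = {"nonsense", "frameshift"}


def table3_fixture_path() -> Path:
    """Path to the packaged nine-variant worked-example table."""
    return Path(str(resources.files("dimerdyn") / "data" / "table3_ano5.tsv"))


def load_variants(path) -> pd.DataFrame:
    """Read a TSV variant table; empty predictor/score cells become absent."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("ada_score", "rf_score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    return df


def predictor_verdict(value: str) -> str:
    """Normalize a predictor string to damaging / benign / absent."""
    v = str(value).strip().lower()
    if not v or v in ("nan", "-", "."):
        return "absent"
    if any(k in v for k in DAMAGING_KEYWORDS):
        return "damaging"
    if any(k in v for k in BENIGN_KEYWORDS):
        return "benign"
    return "absent"


def _parse_maf(value) -> float | None:
    """None = absent (passes the frequency clause); raises on malformed."""
    s = str(value).strip()
    if s in ("", "nan", "-", ".", "0", "0.0"):
        return None
    maf = float(s)  # ValueError propagates to the caller's audit
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF {maf} outside [0, 1]")
    return maf


def n_damaging(row: pd.Series, predictors=DEFAULT_PREDICTORS) -> int:
    return sum(predictor_verdict(row.get(p, "")) == "damaging"
               for p in predictors)


def filter_variants(records: pd.DataFrame,
                    lgmd_gene_panel=DEFAULT_LGMD_PANEL,
                    maf_panel: float = 0.03, maf_other: float = 0.01,
                    predictors=DEFAULT_PREDICTORS,
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the frequency + pathogenicity cascade.

    Returns the retained records and a per-record audit trail stating which
    clause each removed record failed (or the parse error that skipped it).
    """
    if not lgmd_gene_panel:
        raise ValueError("the LGMD gene panel must be non-empty")
    panel = {g.upper() for g in lgmd_gene_panel}
    audit: list[dict] = []
    keep_idx = []
    for idx, row in records.iterrows():
        entry = {"index": int(idx), "gene": row.get("gene", ""),
                 "protein": row.get("protein", ""), "retained": False,
                 "failed": None}
        try:
            maf = _parse_maf(row.get("maf", ""))
        except ValueError as exc:
            entry["failed"] = f"malformed MAF: {exc}"
            audit.append(entry)
            continue
        cutoff = maf_panel if str(row.get("gene", "")).upper() in panel \
            else maf_other
        if maf is not None and maf >= cutoff:
            entry["failed"] = (f"frequency clause: MAF {maf} >= {cutoff}")
            audit.append(entry)
            continue
        if n_damaging(row, predictors) < 1:
            entry["failed"] = "pathogenicity clause: no damaging predictor"
            audit.append(entry)
            continue
        entry["retained"] = True
        keep_idx.append(idx)
        audit.append(entry)
    return records.loc[keep_idx].copy(), audit


def splice_flag(ada_score, rf_score,
                threshold: float = DBSCSNV_THRESHOLD) -> bool:
    """True iff both dbscSNV scores are present and strictly above threshold."""
    ada = None if ada_score is None or pd.isna(ada_score) else float(ada_score)
    rf = None if rf_score is None or pd.isna(rf_score) else float(rf_score)
    if ada is None or rf is None:
        return False
    return ada > threshold and rf > threshold


def rank_variants(retained: pd.DataFrame,
                  predictors=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """Deterministic prioritization of retained records.

    Sort key: truncating (nonsense/frameshift) first, then dbscSNV
    splice-flagged, then missense ordered by damaging-predictor count;
    ties broken by gene symbol then genomic location.
    """
    if len(retained) == 0:
        return retained.copy()

    def tier(row):
        if str(row.get("type", "")).lower() in TRUNCATING_TYPES:
            return 0
        if splice_flag(row.get("ada_score"), row.get("rf_score")):
            return 1
        if str(row.get("type", "")).lower() == "missense":
            return 2
        return 3

    df = retained.copy()
    df["_tier"] = df.apply(tier, axis=1)
    df["_ndmg"] = df.apply(lambda r: n_damaging(r, predictors), axis=1)
    df = df.sort_values(["_tier", "_ndmg", "gene", "location"],
                        ascending=[True, False, True, True],
                        kind="mergesort")
    return df.drop(columns=["_tier", "_ndmg"]).reset_index(drop=True)
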