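"""Lossless CSV/JSON round trips for the analysis result tables."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

OCCUPANCY_COLUMNS = ["res1", "res2", "kind", "occupancy", "label"]


def validate_occupancy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Sorted-descending, deduplicated occupancy table with fixed columns."""
    missing = [c for c in OCCUPANCY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occupancy table missing columns {missing}")
    if len(df) and not df["occupancy"].between(0, 100).all():
        raise ValueError("occupancy values must lie in [0, 100]")
    pairs = df.apply(lambda r: tuple(sorted((r.res1, r.res2))), axis=1)
    if len(df) and pairs.groupby([pairs, df["kind"]]).size().max() > 1:
        raise ValueError("duplicate unordered residue pairs in table")
    return (df[OCCUPANCY_COLUMNS]
            .sort_values(["occupancy", "res1", "res2"],
                         ascending=[False, True, True])
            .reset_index(drop=True))


def save_occupancy_table(df: pd.DataFrame, path) -> None:
    validate_occupancy_table(df).to_csv(path, index=False)


def load_occupancy_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        df = pd.DataFrame(columns=OCCUPANCY_COLUMNS)
        df["res1"] = df["res1"].astype(int)
    return validate_occupancy_table(df)


@dataclass
class ChainSurface:
    n_atoms: int          # interfacing atoms, N(at)
    n_residues: int       # interfacing residues, N(res)
    surface: float        # total accessible surface of the isolated chain, A^2


@dataclass
class InterfaceReport:
    """Interface summary in the PISA table layout.

    ``delta_g_p_value`` is None when the chains are not in contact
    (the p-value is undefined for a zero interface).
    """
    chain_a: ChainSurface
    chain_b: ChainSurface
    interface_area: float          # A^2, (SASA_A + SASA_B - SASA_AB) / 2
    delta_g: float                 # kcal/mol, solvation free-energy gain
    delta_g_p_value: float | None = None

    def __post_init__(self):
        if self.interface_area < -1e-9:
            raise ValueError("interface_area must be non-negative")
        if self.delta_g_p_value is not None and not 0 <= self.delta_g_p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"chain_a": asdict(self.chain_a), "chain_b": asdict(self.chain_b),
                "interface_area": self.interface_area, "delta_g": self.delta_g,
                "delta_g_p_value": self.delta_g_p_value}

    @classmethod
    def from_dict(cls, d: dict) -> "InterfaceReport":
        return cls(chain_a=ChainSurface(**d["chain_a"]),
                   chain_b=ChainSurface(**d["chain_b"]),
                   interface_area=d["interface_area"], delta_g=d["delta_g"],
                   delta_g_p_value=d["delta_g_p_value"])


def save_interface_report(report: InterfaceReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def load_interface_report(path) -> InterfaceReport:
    return InterfaceReport.from_dict(json.loads(Path(path).read_text()))


def modeset_summary(mode_set) -> pd.DataFrame:
    """Eigenvalue spectrum table (the eigenvalue-vs-index plot data)."""
    lam = np.asarray(mode_set.eigenvalues)
    return pd.DataFrame({
        "mode": np.arange(1, len(lam) + 1),
        "eigenvalue_A2": lam,
        "explained_fraction": mode_set.explained_fraction,
        "cumulative_fraction": np.cumsum(mode_set.explained_fraction),
    })


def save_modeset_summary(mode_set, path) -> None:
    modeset_summary(mode_set).to_csv(path, index=False)


def load_modeset_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tables(tables: dict, outdir) -> dict[str, Path]:
    """Write a bundle of result tables; dispatch on value type.

    pandas DataFrames go to CSV, InterfaceReports to JSON, plain dicts to
    JSON.  Returns the mapping name -> written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in tables.items():
        if isinstance(obj, InterfaceReport):
            path = outdir / f"{name}.json"
            save_interface_report(obj, path)
        elif isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False)
        elif isinstance(obj, dict):
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, default=float))
        else:
            raise TypeError(f"cannot serialize table {name!r} of type {type(obj)}")
        written[name] = path
    return written
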