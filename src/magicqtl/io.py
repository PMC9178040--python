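"""Tabular interchange formats for the pipeline.

Everything is plain TSV with named headers (founder probabilities in long
format), plus a JSON file recording the planted ground truth of a
simulation.  Readers validate schemas and report malformed rows with their
line numbers; writers round-trip losslessly with the readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusGroup
from .scan import QTLRecord
from .simulate import (
    FounderProbabilityGrid,
    GeneticMap,
    PhenotypeTable,
    RILPopulation,
    TraitArchitecture,
)


class FormatError(ValueError):
    """A file violated the expected schema; message names file/line/column."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        # +2: one for the header, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}, line {line}: non-numeric value in column {col!r}")
    return vals


# --- genetic map -----------------------------------------------------------

def write_map(gmap: GeneticMap, path) -> None:
    df = gmap.markers[["marker_id", "chrom", "cM"]].copy()
    df["chrom_length_cM"] = df["chrom"].map(gmap.chrom_lengths)
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    _require_columns(df, ["marker_id", "chrom", "cM", "chrom_length_cM"], path)
    df["cM"] = _check_numeric(df, "cM", path)
    lengths = (
        df.drop_duplicates("chrom").set_index("chrom")["chrom_length_cM"].astype(float)
    )
    return GeneticMap(
        df[["marker_id", "chrom", "cM"]].reset_index(drop=True), lengths.to_dict()
    )


# --- genotypes -------------------------------------------------------------

def write_genotypes(pop_or_df, path) -> None:
    df = pop_or_df.genotypes if isinstance(pop_or_df, RILPopulation) else pop_or_df
    out = df.copy()
    out.index.name = "line_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
    bad = ~df.isin([0, 1]).to_numpy() & df.notna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}, line {r + 2}: genotype not in {{0,1,NA}} in column {df.columns[c]!r}"
        )
    return df


# --- funnels ---------------------------------------------------------------

def write_funnels(line_ids, funnel_ids, path) -> None:
    pd.DataFrame({"line_id": line_ids, "funnel_id": funnel_ids}).to_csv(
        path, sep="\t", index=False
    )


def read_funnels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["line_id", "funnel_id"], path)
    if df["line_id"].duplicated().any():
        line = int(df["line_id"].duplicated().idxmax()) + 2
        raise FormatError(f"{path}, line {line}: duplicate line_id")
    return df


# --- phenotypes ------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    _require_columns(df, ["line_id", "trait", "year", "value"], path)
    if "rep" not in df.columns:
        df["rep"] = 1
    df["value"] = _check_numeric(df, "value", path)
    return PhenotypeTable(df[["line_id", "trait", "year", "rep", "value"]])


# --- founder probabilities (long format) -----------------------------------

def write_probability_grid(grid: FounderProbabilityGrid, founder_ids, path) -> None:
    n_l, n_p, n_f = grid.probs.shape
    pos = grid.positions
    df = pd.DataFrame(
        {
            "line_id": np.repeat(grid.line_ids, n_p * n_f),
            "chrom": np.tile(np.repeat(pos["chrom"].to_numpy(), n_f), n_l),
            "grid_cM": np.tile(np.repeat(pos["cM"].to_numpy(), n_f), n_l),
            "founder": np.tile(founder_ids, n_l * n_p),
            "prob": grid.probs.reshape(-1),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_probability_grid(path) -> FounderProbabilityGrid:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["line_id", "chrom", "grid_cM", "founder", "prob"], path)
    df["prob"] = _check_numeric(df, "prob", path)
    line_ids = list(pd.unique(df["line_id"]))
    founders = list(pd.unique(df["founder"]))
    pos = df[["chrom", "grid_cM"]].drop_duplicates().reset_index(drop=True)
    pos = pos.rename(columns={"grid_cM": "cM"})
    pos["cM"] = pos["cM"].astype(float)
    n_l, n_p, n_f = len(line_ids), len(pos), len(founders)
    if len(df) != n_l * n_p * n_f:
        raise FormatError(f"{path}: probability table is not a complete grid")
    probs = df["prob"].to_numpy().reshape(n_l, n_p, n_f)
    bad = np.abs(probs.sum(axis=2) - 1.0) > 1e-6
    if bad.any():
        raise FormatError(f"{path}: founder probabilities do not sum to 1 everywhere")
    return FounderProbabilityGrid(pos, probs, line_ids)


# --- ground truth ----------------------------------------------------------

def write_truth(arch: TraitArchitecture, path) -> None:
    payload = {
        "trait_ids": arch.trait_ids,
        "h2": np.asarray(arch.h2).tolist(),
        "funnel_var": arch.funnel_var,
        "qtls": [
            {
                "chrom": q.chrom,
                "pos_cM": q.pos_cM,
                "mode": q.mode,
                "trait_effects": np.asarray(q.trait_effects).tolist(),
                "year_multipliers": np.asarray(q.year_multipliers).tolist(),
                "founder_pattern": (
                    np.asarray(q.founder_pattern).tolist()
                    if q.founder_pattern is not None
                    else None
                ),
            }
            for q in arch.qtls
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# --- QTL records -----------------------------------------------------------

_QTL_COLUMNS = [
    "trait", "year", "method", "source", "chrom", "peak_cM", "peak_label",
    "p_add", "p_fdr", "confidence", "left_cM", "left_label", "right_cM",
    "right_label", "pve", "total_pve", "effect",
] + [f"founder_eff_{i + 1}" for i in range(8)]


def qtl_frame(records: list[QTLRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _QTL_COLUMNS[:17]}
        for i, v in enumerate(np.asarray(r.founder_effects, dtype=float)):
            row[f"founder_eff_{i + 1}"] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=_QTL_COLUMNS)


def write_qtl(records: list[QTLRecord], path) -> None:
    qtl_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_qtl(path) -> list[QTLRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    _require_columns(df, _QTL_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        records.append(
            QTLRecord(
                trait=str(row["trait"]),
                year=row["year"],
                method=str(row["method"]),
                source=str(row["source"]),
                chrom=str(row["chrom"]),
                peak_cM=float(row["peak_cM"]),
                peak_label=str(row["peak_label"]),
                p_add=float(row["p_add"]),
                p_fdr=float(row["p_fdr"]),
                confidence=str(row["confidence"]),
                left_cM=None if pd.isna(row["left_cM"]) else float(row["left_cM"]),
                left_label=None if pd.isna(row["left_label"]) else str(row["left_label"]),
                right_cM=None if pd.isna(row["right_cM"]) else float(row["right_cM"]),
                right_label=None if pd.isna(row["right_label"]) else str(row["right_label"]),
                pve=float(row["pve"]),
                total_pve=float(row["total_pve"]),
                effect=float(row["effect"]),
                founder_effects=np.array(
                    [row[f"founder_eff_{i + 1}"] for i in range(8)], dtype=float
                ),
            )
        )
    return records


# --- consensus groups ------------------------------------------------------

def write_consensus(groups: list[ConsensusGroup], path) -> None:
    rows = []
    for g in groups:
        for m in g.members:
            rows.append(
                {
                    "group_id": g.group_id,
                    "chrom": g.chrom,
                    "median_peak_cM": g.median_peak_cM,
                    "trait": m.trait,
                    "year": m.year,
                    "method": m.method,
                    "peak_cM": m.peak_cM,
                    "confidence": m.confidence,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "group_id", "chrom", "median_peak_cM", "trait", "year", "method",
            "peak_cM", "confidence",
        ],
    ).to_csv(path, sep="\t", index=False)
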