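"""Plain-text readers and writers for every pipeline artifact.

All tables are TSV with a header row; gene-set collections use the
standard GMT layout (set name, description, tab-separated members);
manifests and curve exports may additionally be JSON. Every writer has
a reader inverse (write then read returns an equal object).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from regenatlas.de import Comparison, CountMatrix, PairwiseDEResult
from regenatlas.design import TimepointDesign
from regenatlas.enrichment import EnrichmentCurve, GeneSet, HomologyMap, ORAResult
from regenatlas.patterns import BinaryMatrix
from regenatlas.synthetic import SimulationTruth


# ---------------------------------------------------------------- counts

def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    design = read_design_frame(design_path)
    df = pd.read_csv(counts_path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(
            f"{counts_path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    if df["gene_id"].duplicated().any():
        dupes = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"{counts_path}: duplicate gene id {dupes!r}")
    df = df.set_index("gene_id")
    df.index.name = None
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{counts_path}: non-integer count in column {col!r}, line {line}"
            )
        df[col] = numeric.astype(np.int64)
    return CountMatrix(counts=df, design=design)


# ---------------------------------------------------------------- design

def write_design(design: TimepointDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    required = {"sample_id", "timepoint", "order"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in design")
    return frame


def read_design(path: str | Path) -> TimepointDesign:
    return TimepointDesign.from_frame(read_design_frame(path))


# ----------------------------------------------------------------- truth

def write_truth(truth: SimulationTruth, genes_path: str | Path,
                size_factors_path: str | Path | None = None) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index=False)
    if size_factors_path is not None:
        truth.size_factors.rename_axis("sample_id").reset_index().to_csv(
            size_factors_path, sep="\t", index=False
        )


def read_truth(genes_path: str | Path, design: TimepointDesign,
               size_factors_path: str | Path | None = None) -> SimulationTruth:
    genes = pd.read_csv(
        genes_path, sep="\t", dtype={"gene_id": str, "pattern": str}
    )
    if size_factors_path is not None:
        sf_tab = pd.read_csv(size_factors_path, sep="\t", dtype={"sample_id": str})
        sf = sf_tab.set_index("sample_id")["size_factor"]
    else:
        sf = pd.Series(1.0, index=design.sample_ids, name="size_factor")
    return SimulationTruth(genes=genes, size_factors=sf, design=design)


# ------------------------------------------------------------------- GMT

def write_gmt(genesets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    f"and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not name or not members:
                raise ValueError(f"{path}: line {lineno}: empty set name or members")
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(
                GeneSet(name=name, members=frozenset(members), description=description)
            )
    return sets


# --------------------------------------------------------------- mapping

def write_mapping(homology: HomologyMap, path: str | Path) -> None:
    rows = [
        {"symbol": sym, "gene_id": gid}
        for sym in sorted(homology.associations)
        for gid in sorted(homology.associations[sym])
    ]
    pd.DataFrame(rows, columns=["symbol", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_mapping(path: str | Path) -> HomologyMap:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"symbol", "gene_id"} <= set(tab.columns):
        raise ValueError(f"{path}: mapping requires columns symbol, gene_id")
    bad = tab["symbol"].isna() | tab["gene_id"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: empty field on line {line}")
    return HomologyMap.from_pairs(list(zip(tab["symbol"], tab["gene_id"])))


# -------------------------------------------------------------- DE table

def write_de_table(result: PairwiseDEResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_de_table(
    path: str | Path, comparison: Comparison, fdr_threshold: float = 0.05
) -> PairwiseDEResult:
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2_fold_change", "p_value", "fdr", "direction"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    if tab["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in DE table")
    return PairwiseDEResult(
        comparison=comparison, table=tab, fdr_threshold=fdr_threshold
    )


def comparison_from_name(name: str) -> Comparison:
    """Inverse of Comparison.name ('A1+A2_vs_B1')."""
    try:
        left, right = name.split("_vs_")
    except ValueError:
        raise ValueError(f"malformed comparison name {name!r}") from None
    return Comparison(group_a=tuple(left.split("+")), group_b=tuple(right.split("+")))


# --------------------------------------------------------- binary matrix

def write_binary_matrix(matrix: BinaryMatrix, path: str | Path,
                        provenance_path: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(matrix.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_binary_matrix(path: str | Path,
                       provenance_path: str | Path | None = None) -> BinaryMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("gene_id")
    df.index.name = None
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids in binary matrix")
    provenance = {}
    if provenance_path is not None:
        with open(provenance_path) as fh:
            provenance = json.load(fh)
    return BinaryMatrix(values=df, provenance=provenance)


# ---------------------------------------------------------------- curves

def write_curves(curves: list[EnrichmentCurve], path: str | Path) -> None:
    frames = []
    for curve in curves:
        tab = curve.table.copy()
        tab.insert(0, "set_name", curve.set_name)
        tab["ci_level"] = curve.ci_level
        tab["set_size"] = curve.effective_set_size
        tab["universe_size"] = curve.universe_size
        frames.append(tab)
    columns = [
        "set_name", "timepoint", "raw_percent", "baseline_percent",
        "band_low_percent", "band_high_percent", "adjusted_percent",
        "ci_level", "set_size", "universe_size",
    ]
    if frames:
        pd.concat(frames, ignore_index=True)[columns].to_csv(
            path, sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=columns).to_csv(path, sep="\t", index=False)


def read_curves(path: str | Path) -> list[EnrichmentCurve]:
    tab = pd.read_csv(path, sep="\t", dtype={"set_name": str, "timepoint": str})
    curves = []
    for name, grp in tab.groupby("set_name", sort=False):
        curves.append(
            EnrichmentCurve(
                set_name=name,
                table=grp.drop(
                    columns=["set_name", "ci_level", "set_size", "universe_size"]
                ).reset_index(drop=True),
                ci_level=str(grp["ci_level"].iloc[0]),
                effective_set_size=int(grp["set_size"].iloc[0]),
                universe_size=int(grp["universe_size"].iloc[0]),
            )
        )
    return curves


def write_curves_json(curves: list[EnrichmentCurve], path: str | Path) -> None:
    payload = [
        {
            "set_name": c.set_name,
            "ci_level": c.ci_level,
            "set_size": c.effective_set_size,
            "universe_size": c.universe_size,
            "points": c.table.to_dict(orient="records"),
        }
        for c in curves
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ------------------------------------------------------------------- ORA

def write_ora(result: ORAResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- manifest

def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
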