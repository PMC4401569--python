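"""Text I/O: expression/design/phenotype TSV, GMT annotation, configs.

Everything the pipeline writes is plain TSV (genes x samples with a
``gene_id`` first column; missing values as ``NA``) so artifacts can be
diffed, versioned and re-read losslessly — writes use Python's shortest
round-trip float representation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_gmt",
    "write_gmt",
    "write_results_tsv",
    "read_geo_series_matrix",
    "validate_design",
    "PipelineConfig",
]

_DESIGN_COLUMNS = ["sample_id", "strain", "regime", "time_h", "replicate"]


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def read_expression_tsv(path, scale: str = "linear") -> pd.DataFrame:
    mat = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False
    )
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dup[:5]}")
    if mat.columns.has_duplicates:
        raise ValueError("duplicate sample IDs")
    mat = mat.astype(float)
    mat.attrs["scale"] = scale
    return mat


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design[_DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    missing = [c for c in _DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in design table")
    return design


def validate_design(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    """Every design sample must exist in the matrix and vice versa."""
    mat_samples = set(matrix.columns)
    des_samples = set(design["sample_id"])
    unknown = des_samples - mat_samples
    if unknown:
        raise ValueError(f"design references unknown samples: {sorted(unknown)}")
    orphan = mat_samples - des_samples
    if orphan:
        raise ValueError(f"matrix samples absent from design: {sorted(orphan)}")


def write_phenotype_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t")
    for col in ("strain", "regime"):
        if col not in phen.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    return phen


def read_gmt(path) -> tuple[dict[str, set], dict[str, str]]:
    """GMT: one category per line — name, description, tab-separated members."""
    categories: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln}: need name, description, >=1 member")
            name, desc, *members = parts
            if name in categories:
                raise ValueError(f"duplicate GMT category {name!r}")
            categories[name] = set(members)
            descriptions[name] = desc
    return categories, descriptions


def write_gmt(categories: Mapping[str, set], descriptions: Mapping[str, str], path):
    with open(path, "w") as fh:
        for name, members in categories.items():
            fh.write(
                "\t".join([name, descriptions.get(name, ""), *sorted(members)]) + "\n"
            )


def write_results_tsv(frame: pd.DataFrame, path, header_note: str | None = None):
    """Result table with an optional ``#``-prefixed provenance header line."""
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        frame.to_csv(fh, sep="\t", na_rep="NA")


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Reader for a GEO series-matrix-style text file (offline, table only).

    Metadata lines start with ``!``; the expression block sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    """
    rows: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if in_table and stripped:
                rows.append([f.strip('"') for f in stripped.split("\t")])
    if not rows:
        raise ValueError("no series-matrix table block found")
    header, *data = rows
    mat = pd.DataFrame(data, columns=header).set_index(header[0])
    mat = mat.replace({"null": None, "": None}).astype(float)
    mat.index.name = "gene_id"
    mat.attrs["scale"] = "linear"
    return mat


@dataclasses.dataclass
class PipelineConfig:
    """All inputs and thresholds for one end-to-end run.

    When ``matrix_path`` is None the run starts from the synthetic
    generator using the simulation fields.  Defaults are the analysis'
    standard thresholds: 75% presence, k = 10, BH FDR 0.05, |rho| > 0.6
    with p < 0.05, RP alpha 0.05, candidate/final folds 3 and 4,
    enrichment p < 0.001.
    """

    out_dir: str = "results/run"
    matrix_path: str | None = None
    design_path: str | None = None
    phenotype_path: str | None = None
    gmt_path: str | None = None
    # simulation (used when matrix_path is None)
    n_genes: int = 5764
    missing_rate: float = 0.03
    noise_sd_log2: float = 0.25
    # thresholds
    presence_min_fraction: float = 0.75
    knn_k: int = 10
    anova_fdr: float = 0.05
    rho_threshold: float = 0.6
    corr_p_threshold: float = 0.05
    rp_alpha: float = 0.05
    fold_thresholds: tuple[float, float] = (3.0, 4.0)
    enrichment_p: float = 0.001
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.presence_min_fraction <= 1:
            raise ValueError("presence_min_fraction must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        for name in ("anova_fdr", "corr_p_threshold", "rp_alpha", "enrichment_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in (0, 1)")
        lo, hi = self.fold_thresholds
        if not 1 < lo <= hi:
            raise ValueError("fold_thresholds must satisfy 1 < candidate <= final")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fold_thresholds" in data:
            data["fold_thresholds"] = tuple(data["fold_thresholds"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["fold_thresholds"] = list(self.fold_thresholds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
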