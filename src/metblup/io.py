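"""Delimited-text readers and writers for every table the pipeline touches.

All interchange is plain delimited text (comma by default, tab accepted):
long-format phenotypes (genotype, environment, value), marker dosage tables
(genotypes x loci), square relationship matrices with an id header row and
column, env-value tables, metric tables and variance components.  Identifier
matching is exact-string and case-sensitive throughout; mismatches are
errors, never silent drops.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import VarianceComponents
from .metrics import EnvBVMatrix
from .simdata import MarkerPanel, RelationshipMatrix, SimScenario

__all__ = [
    "read_phenotypes",
    "read_markers",
    "read_grm",
    "read_markers_or_grm",
    "read_env_values",
    "read_scenario",
    "write_phenotypes",
    "write_markers",
    "write_grm",
    "write_env_values",
    "write_components",
    "read_components",
]

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("genotype", "environment", "value")


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


def _read_table(path, index_col=None):
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def _check_header(path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = [c.strip() for c in header.split(sep)]
    dupes = {c for c in names if names.count(c) > 1}
    if dupes:
        raise SchemaError(f"duplicated header column(s): {sorted(dupes)}")
    return names


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotypes; duplicate (genotype, environment) rows are kept
    as replicate plots, blank values are dropped with a logged count."""
    names = _check_header(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in names]
    if missing:
        raise SchemaError(f"phenotype file is missing column(s): {missing}")
    df = _read_table(path)
    blank = df["value"].isna()
    if blank.any():
        log.info("dropped %d phenotype rows with blank values", int(blank.sum()))
        df = df[~blank]
    try:
        values = pd.to_numeric(df["value"])
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()][0]
        raise ValueError(
            f"non-numeric phenotype value on data line {bad + 2} of {path}"
        ) from None
    out = df.loc[:, ["genotype", "environment"]].astype(str)
    out["value"] = values.to_numpy(dtype=float)
    out["observed"] = True
    return out.reset_index(drop=True)


def read_markers(path) -> MarkerPanel:
    """Dosage table: first column genotype ids, remaining columns loci."""
    df = _read_table(path, index_col=0)
    dosages = df.to_numpy()
    bad = ~np.isin(dosages, (0, 1, 2))
    if bad.any():
        i, m = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage {dosages[i, m]!r} outside {{0,1,2}} at locus {df.columns[m]!r}"
        )
    return MarkerPanel(
        genotype_ids=[str(g) for g in df.index],
        locus_ids=[str(m) for m in df.columns],
        dosages=dosages.astype(np.int64),
    )


def read_grm(path) -> RelationshipMatrix:
    """Square relationship matrix with matching id header row and column.

    Asymmetries below 1e-6 are symmetrized by averaging; larger ones are an
    error.
    """
    df = _read_table(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"relationship matrix is not square: {df.shape}")
    if [str(i) for i in df.index] != [str(c) for c in df.columns]:
        raise ValueError("relationship matrix row and column ids disagree")
    A = df.to_numpy(dtype=float)
    asym = np.abs(A - A.T).max()
    if asym > 1e-6:
        raise ValueError(f"relationship matrix asymmetry {asym:.2e} exceeds 1e-6")
    return RelationshipMatrix(A=(A + A.T) / 2.0, genotype_ids=[str(g) for g in df.index])


def read_markers_or_grm(path, kind: str) -> MarkerPanel | RelationshipMatrix:
    if kind == "markers":
        return read_markers(path)
    if kind == "grm":
        return read_grm(path)
    raise ValueError(f"kind must be 'markers' or 'grm', got {kind!r}")


def read_env_values(path) -> EnvBVMatrix:
    """Genotypes x environments value table (e.g. adjusted means)."""
    df = _read_table(path, index_col=0)
    return EnvBVMatrix(
        values=df.to_numpy(dtype=float),
        genotype_ids=[str(g) for g in df.index],
        environment_ids=[str(e) for e in df.columns],
    )


def read_scenario(path) -> SimScenario:
    """Simulation scenario from a YAML mapping of SimScenario fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimScenario(**raw)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    """Observed rows only, columns genotype/environment/value."""
    out = df[df["observed"]] if "observed" in df.columns else df
    out.loc[:, ["genotype", "environment", "value"]].to_csv(path, index=False)


def write_markers(panel: MarkerPanel, path) -> None:
    pd.DataFrame(
        panel.dosages, index=panel.genotype_ids, columns=panel.locus_ids
    ).to_csv(path, index_label="genotype")


def write_grm(rel: RelationshipMatrix, path) -> None:
    pd.DataFrame(
        rel.A, index=rel.genotype_ids, columns=rel.genotype_ids
    ).to_csv(path, index_label="genotype")


def write_env_values(G: EnvBVMatrix, path) -> None:
    pd.DataFrame(
        G.values, index=G.genotype_ids, columns=G.environment_ids
    ).to_csv(path, index_label="genotype")


def write_components(vc: VarianceComponents, out_dir) -> None:
    out_dir = Path(out_dir)
    ids = vc.environment_ids
    pd.DataFrame(vc.omega_G, index=ids, columns=ids).to_csv(
        out_dir / "omega_G.csv", index_label="environment"
    )
    pd.DataFrame({"environment": ids, "sigma2_E": vc.sigma2_E}).to_csv(
        out_dir / "omega_E.csv", index=False
    )


def read_components(out_dir) -> VarianceComponents:
    out_dir = Path(out_dir)
    og = _read_table(out_dir / "omega_G.csv", index_col=0)
    oe = _read_table(out_dir / "omega_E.csv")
    if list(og.index.astype(str)) != list(oe["environment"].astype(str)):
        raise ValueError("omega_G and omega_E environment ids disagree")
    return VarianceComponents(
        omega_G=og.to_numpy(dtype=float),
        sigma2_E=oe["sigma2_E"].to_numpy(dtype=float),
        environment_ids=[str(e) for e in og.index],
    )
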