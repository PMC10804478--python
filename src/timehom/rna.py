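"""Immune-cell abundance from bulk RNA-seq via marker-gene-set averaging.

The abundance of an immune cell type in a bulk sample is estimated as the
unweighted mean of the normalized expression of its marker genes.  The
same machinery scores immune-related pathway panels (antigen presentation,
cell adhesion, co-stimulators/-inhibitors, cytokines, receptors, ligands):
a panel is just another gene set.

Counts are read from a featureCounts-style gene x sample matrix.  The
default normalization is log2(CPM + 1); linear CPM and raw counts are
selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NORMALIZATIONS = ("log2cpm", "cpm", "raw")


@dataclass
class AbundanceMatrix:
    """Feature x sample abundances plus provenance of the computation."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def load_gene_sets(path) -> dict[str, list[str]]:
    """Read a feature -> gene-list mapping from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate_gene_sets(raw)


def default_gene_sets() -> dict[str, list[str]]:
    """Packaged default marker-gene map (user-overridable, never mandatory)."""
    text = resources.files("timehom.data").joinpath("gene_sets.yaml").read_text()
    return _validate_gene_sets(yaml.safe_load(text))


def _validate_gene_sets(raw: Mapping) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for feat, genes in raw.items():
        genes = list(genes)
        if len(genes) == 0:
            raise ValueError(f"gene set {feat!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {feat!r} has duplicate gene ids")
        out[str(feat)] = [str(g) for g in genes]
    return out


def normalize_counts(counts: pd.DataFrame, method: str = "log2cpm") -> pd.DataFrame:
    """Normalize a gene x sample count matrix.

    ``log2cpm`` (default): counts-per-million per sample, then log2(x+1).
    ``cpm``: linear counts-per-million.  ``raw``: counts cast to float.
    Raises on negative counts and on all-zero samples (naming the sample).
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}; choose from {NORMALIZATIONS}")
    if counts.shape[1] < 1:
        raise ValueError("count matrix has no samples")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("count matrix contains negative values")
    if method == "raw":
        return counts.astype(float)
    libsize = values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = [str(counts.columns[i]) for i in zero]
        raise ValueError(f"sample(s) with zero total counts: {names}")
    cpm = values / libsize * 1e6
    if method == "cpm":
        return pd.DataFrame(cpm, index=counts.index, columns=counts.columns)
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def gene_set_abundance(
    normalized: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    strict: bool = False,
    normalization: str | None = None,
) -> AbundanceMatrix:
    """Average each feature's present marker genes per sample.

    Missing genes are recorded in the provenance; a feature with no gene
    present in the matrix raises in ``strict`` mode and is dropped with a
    warning otherwise.
    """
    gene_sets = _validate_gene_sets(gene_sets)
    rows = {}
    prov: dict[str, dict] = {"normalization": normalization, "features": {}}
    index = pd.Index(normalized.index)
    for feat, genes in gene_sets.items():
        present = [g for g in genes if g in index]
        missing = [g for g in genes if g not in index]
        prov["features"][feat] = {"genes_found": present, "genes_missing": missing}
        if not present:
            msg = f"feature {feat!r}: none of its genes {genes} are in the matrix"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; feature dropped", stacklevel=2)
            continue
        rows[feat] = normalized.loc[present].mean(axis=0)
    data = pd.DataFrame(rows).T
    if data.empty:
        data = pd.DataFrame(columns=normalized.columns)
    data.columns = normalized.columns
    return AbundanceMatrix(data=data, provenance=prov)


def pathway_panel_scores(
    normalized: pd.DataFrame,
    panels: Mapping[str, Sequence[str]],
    strict: bool = False,
    normalization: str | None = None,
) -> AbundanceMatrix:
    """Score immune-related pathway panels; identical averaging machinery."""
    if len(panels) == 0:
        return AbundanceMatrix(
            data=pd.DataFrame(columns=normalized.columns),
            provenance={"normalization": normalization, "features": {}},
        )
    return gene_set_abundance(normalized, panels, strict=strict, normalization=normalization)
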