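"""Annotation filtering and coverage-normalised abundance matrices.

A family's abundance in a sample is the sum, over secreted annotated genes
carrying that family, of the host contig's mean read depth, scaled by
1e9 / total assembly length (depth per gigabase of assembly). The absolute
scale is a convention; every downstream statistic used for interpretation
(necromass fraction, ranks, ordination) is invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from thermenz.io import GeneAnnotation

NORMALIZATION_SCALE = 1e9  # depth per gigabase of assembly

#: callers whose joint support is required for a CAZY annotation to pass
TWO_TOOL_CALLERS = frozenset({"HMMER", "DIAMOND"})


@dataclass
class AbundanceMatrix:
    """Family x sample matrix of normalised abundances for one scheme."""

    scheme: str
    data: pd.DataFrame  # index: families, columns: samples

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate family labels")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample labels")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative abundance")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "family"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scheme: str) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(scheme=scheme, data=df)


def filter_annotations(
    annots: list[GeneAnnotation],
    secreted_only: bool = True,
    min_two_tools: bool = True,
    ec_hydrolases_only: bool = True,
) -> list[GeneAnnotation]:
    """Apply the study's selection rules.

    - ``secreted_only``: keep only genes with a predicted signal peptide
      (all schemes).
    - ``min_two_tools``: CAZY annotations must be supported by both HMMER
      and DIAMOND. Other schemes come from a single annotator and are not
      subject to this rule.
    - ``ec_hydrolases_only``: EC records keep only class-3 labels
      (hydrolases); records left without labels are dropped.
    """
    out = []
    for a in annots:
        if secreted_only and not a.secreted:
            continue
        if min_two_tools and a.scheme == "CAZY":
            if not TWO_TOOL_CALLERS <= a.tool_support:
                continue
        if ec_hydrolases_only and a.scheme == "EC":
            kept = tuple(lab for lab in a.labels if lab.startswith("3."))
            if not kept:
                continue
            if kept != a.labels:
                a = GeneAnnotation(a.gene_id, a.scheme, kept, a.tool_support,
                                   a.secreted, a.contig_id)
        out.append(a)
    return out


def gene_abundance(gene_id: str, gene_map: dict[str, str],
                   coverage: dict[str, float]) -> float:
    """Mean read depth of the contig hosting ``gene_id``."""
    contig = gene_map.get(gene_id)
    if contig is None:
        raise KeyError(f"gene {gene_id!r} not present in the gene map")
    if contig not in coverage:
        raise KeyError(f"gene {gene_id!r}: contig {contig!r} missing from coverage")
    return coverage[contig]


def build_matrix(
    annotations: dict[str, list[GeneAnnotation]],
    coverages: dict[str, dict[str, float]],
    assembly_lengths: dict[str, int],
    scheme: str,
) -> AbundanceMatrix:
    """Accumulate filtered annotations into a family x sample matrix.

    ``annotations`` maps sample id -> annotations with ``contig_id``
    resolved (see :func:`thermenz.io.attach_contigs`); ``coverages`` maps
    sample id -> {contig: mean depth}. Each gene contributes its contig's
    mean depth once per family label it carries. Samples with zero passing
    annotations appear as all-zero columns.
    """
    samples = list(assembly_lengths)
    cells: dict[str, dict[str, float]] = {}
    for sample, annots in annotations.items():
        if sample not in assembly_lengths:
            raise KeyError(f"no assembly stats for sample {sample!r}")
        total = assembly_lengths[sample]
        cov = coverages[sample]
        scale = NORMALIZATION_SCALE / total
        for a in annots:
            if a.scheme != scheme:
                continue
            if a.contig_id is None:
                raise ValueError(f"gene {a.gene_id}: contig not resolved")
            if a.contig_id not in cov:
                raise KeyError(
                    f"gene {a.gene_id}: contig {a.contig_id!r} missing from coverage"
                )
            depth = cov[a.contig_id]
            for fam in a.labels:
                cells.setdefault(fam, {}).setdefault(sample, 0.0)
                cells[fam][sample] += depth * scale
    families = sorted(cells)
    data = pd.DataFrame(0.0, index=families, columns=samples)
    for fam, per_sample in cells.items():
        for sample, val in per_sample.items():
            data.at[fam, sample] = val
    return AbundanceMatrix(scheme=scheme, data=data)


def prevalence_filter(matrix: AbundanceMatrix, min_frac: float = 0.75) -> AbundanceMatrix:
    """Drop families detected (abundance > 0) in fewer than
    ceil(min_frac * n_samples) samples."""
    if not 0 <= min_frac <= 1:
        raise ValueError(f"min_frac {min_frac} outside [0, 1]")
    n = len(matrix.samples)
    threshold = max(1, math.ceil(min_frac * n))
    present = (matrix.data > 0).sum(axis=1)
    return AbundanceMatrix(scheme=matrix.scheme,
                           data=matrix.data.loc[present >= threshold].copy())


def viz_transform(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Display transform log10(x + 0.5); never used for correlations."""
    return np.log10(matrix.data + 0.5)
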