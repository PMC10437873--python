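"""Substrate-group scoring: cell necromass vs photosynthate degradation.

Enzyme families are assigned to substrate groups (chitin, peptidoglycan,
starch/glycogen, trehalose, xylan, cellulose). The *cell* supergroup
(chitin + peptidoglycan) tracks degradation of dead microbial biomass; the
*photosynthate* supergroup (xylan + cellulose) tracks plant/algal material.
The necromass fraction cell / (cell + photosynthate) summarises, per
sample, how strongly the secreted enzyme repertoire leans toward recycling
in-situ cell material rather than surface-derived photosynthate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from importlib import resources

import numpy as np
import pandas as pd

from thermenz.abundance import AbundanceMatrix
from thermenz.io import SiteMetadata, sample_type_from_id

SUPERGROUPS = {
    "cell": ("chitin", "peptidoglycan"),
    "photosynthate": ("xylan", "cellulose"),
}


def _data_path(name: str):
    return resources.files("thermenz.data").joinpath(name)


@dataclass
class SubstrateGroupMap:
    """group -> {(scheme, family)} assignments.

    Families may belong to several groups (GH5 sits in chitin, xylan and
    cellulose), so supergroup sums deduplicate families within a
    supergroup while a family shared across the two supergroups counts in
    both (``dedup='within-supergroup'``) or in neither
    (``dedup='exclusive'``).
    """

    assignments: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "SubstrateGroupMap":
        df = pd.read_csv(path, sep="\t")
        out: dict[str, set[tuple[str, str]]] = {}
        for _, row in df.iterrows():
            out.setdefault(row["group"], set()).add((row["scheme"], row["family"]))
        return cls(out)

    def families(self, group: str, scheme: str | None = None) -> set[str]:
        members = self.assignments.get(group, set())
        return {fam for sch, fam in members if scheme is None or sch == scheme}

    def supergroup_families(
        self,
        supergroup: str,
        schemes: tuple[str, ...] = ("CAZY",),
        dedup: str = "within-supergroup",
    ) -> set[str]:
        """Distinct family labels of a supergroup, restricted to ``schemes``."""
        if supergroup not in SUPERGROUPS:
            raise KeyError(
                f"unknown supergroup {supergroup!r}; expected one of {sorted(SUPERGROUPS)}"
            )
        if dedup not in {"within-supergroup", "exclusive"}:
            raise ValueError(f"unknown dedup mode {dedup!r}")
        fams: set[str] = set()
        for group in SUPERGROUPS[supergroup]:
            for scheme in schemes:
                fams |= self.families(group, scheme)
        if dedup == "exclusive":
            other = "photosynthate" if supergroup == "cell" else "cell"
            other_fams: set[str] = set()
            for group in SUPERGROUPS[other]:
                for scheme in schemes:
                    other_fams |= self.families(group, scheme)
            fams -= other_fams
        return fams


def default_substrate_map() -> SubstrateGroupMap:
    """The packaged substrate-group map (CAZy + MEROPS family assignments)."""
    with resources.as_file(_data_path("substrate_groups.tsv")) as p:
        return SubstrateGroupMap.from_tsv(p)


def load_printed_scores() -> pd.DataFrame:
    """The packaged per-sample cell/photosynthate score table of the
    63-spring geothermal survey (100 assemblies), with the fractions as
    printed to 2 d.p."""
    with resources.as_file(_data_path("study_necromass_scores.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def load_study_sites() -> pd.DataFrame:
    """The packaged site-metadata table of the geothermal survey
    (63 sites; 'NM' marks unmeasured temperature/pH)."""
    with resources.as_file(_data_path("study_sites.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["NM"])


def load_reported_family_counts() -> dict:
    """Secreted family counts per MEROPS catalytic type and per CAZy class
    reported for the survey."""
    with resources.as_file(_data_path("reported_family_counts.json")) as p:
        return json.loads(p.read_text())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def group_abundance(
    matrices: dict[str, AbundanceMatrix] | AbundanceMatrix,
    gmap: SubstrateGroupMap,
    supergroup: str,
    schemes: tuple[str, ...] = ("CAZY",),
    dedup: str = "within-supergroup",
) -> pd.Series:
    """Per-sample summed abundance of a supergroup's distinct families.

    A family belonging to two member groups of the same supergroup (GH5 in
    both xylan and cellulose) is counted once. Pools across the schemes
    requested; by default only CAZy families enter the score.
    """
    if isinstance(matrices, AbundanceMatrix):
        matrices = {matrices.scheme: matrices}
    total: pd.Series | None = None
    for scheme in schemes:
        if scheme not in matrices:
            continue
        m = matrices[scheme]
        fams = gmap.supergroup_families(supergroup, (scheme,), dedup=dedup)
        hit = [f for f in m.families if f in fams]
        part = m.data.loc[hit].sum(axis=0)
        total = part if total is None else total.add(part, fill_value=0.0)
    if total is None:
        raise ValueError(f"no matrices for schemes {schemes}")
    return total


def necromass_fraction(cell, photo):
    """cell / (cell + photo); NaN where both are zero.

    Accepts scalars or aligned arrays/Series. Negative inputs are an
    error, not a silent NaN.
    """
    c = np.asarray(cell, dtype=float)
    p = np.asarray(photo, dtype=float)
    if (c < 0).any() or (p < 0).any():
        raise ValueError("negative abundance passed to necromass_fraction")
    denom = c + p
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, c / np.where(denom > 0, denom, 1.0), np.nan)
    if np.ndim(cell) == 0 and np.ndim(photo) == 0:
        return float(frac)
    if isinstance(cell, pd.Series):
        return pd.Series(frac, index=cell.index)
    return frac


def round_fraction(value: float, ndigits: int = 2) -> float:
    """Round-half-even to ``ndigits`` decimals, the table convention."""
    if np.isnan(value):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def score_table(
    matrices: dict[str, AbundanceMatrix] | AbundanceMatrix,
    gmap: SubstrateGroupMap,
    metadata: list[SiteMetadata] | None = None,
    schemes: tuple[str, ...] = ("CAZY",),
    dedup: str = "within-supergroup",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample cell/photosynthate sums and necromass fraction.

    Returns the table sorted by necromass fraction ascending plus the grand
    totals of the two columns. Samples whose cell and photosynthate sums
    are both zero carry a NaN fraction and sort last.
    """
    cell = group_abundance(matrices, gmap, "cell", schemes, dedup)
    photo = group_abundance(matrices, gmap, "photosynthate", schemes, dedup)
    photo = photo.reindex(cell.index, fill_value=0.0)

    meta_by_sample: dict[str, SiteMetadata] = {}
    if metadata is not None:
        for m in metadata:
            meta_by_sample[m.sample_name] = m
            meta_by_sample.setdefault(m.abbrev, m)

    rows = []
    for sample in cell.index:
        if metadata is not None and sample not in meta_by_sample:
            raise KeyError(f"sample {sample!r} missing from metadata")
        meta = meta_by_sample.get(sample)
        rows.append({
            "sample_id": sample,
            "cell": float(cell[sample]),
            "photosynthate": float(photo[sample]),
            "province": meta.province if meta else "",
            "sample_type": (meta.sample_type if meta else None) or sample_type_from_id(sample),
            "temperature": meta.temperature if meta else None,
            "pH": meta.pH if meta else None,
            "necromass_fraction": necromass_fraction(float(cell[sample]), float(photo[sample])),
        })
    columns = ["sample_id", "cell", "photosynthate", "province", "sample_type",
               "temperature", "pH", "necromass_fraction"]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["necromass_fraction", "sample_id"], na_position="last",
                        kind="mergesort").reset_index(drop=True)
    totals = {"cell": float(df["cell"].sum()),
              "photosynthate": float(df["photosynthate"].sum())}
    return df, totals


def fluid_sediment_summary(scores: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Stacked cell/photosynthate sums per (province, sample type).

    Also returns the global fluid-vs-sediment comparison: total cell and
    photosynthate abundance in each sample type, as a simple sum
    comparison of where each supergroup is more abundant.
    """
    df = scores.copy()
    if "sample_type" not in df or df["sample_type"].isna().all():
        df["sample_type"] = df["sample_id"].map(sample_type_from_id)
    df["sample_type"] = df["sample_type"].str.lower().map(
        {"fluid": "fluid", "sediment": "sediment", "f": "fluid", "s": "sediment"})
    grouped = (
        df.groupby(["province", "sample_type"], dropna=False)[["cell", "photosynthate"]]
        .sum()
        .reset_index()
    )
    by_type = df.groupby("sample_type")[["cell", "photosynthate"]].sum()
    global_comparison = {
        "cell_fluid": float(by_type.at["fluid", "cell"]) if "fluid" in by_type.index else 0.0,
        "cell_sediment": float(by_type.at["sediment", "cell"]) if "sediment" in by_type.index else 0.0,
        "photosynthate_fluid": float(by_type.at["fluid", "photosynthate"]) if "fluid" in by_type.index else 0.0,
        "photosynthate_sediment": float(by_type.at["sediment", "photosynthate"]) if "sediment" in by_type.index else 0.0,
    }
    global_comparison["photosynthate_richer_in_sediments"] = (
        global_comparison["photosynthate_sediment"] > global_comparison["photosynthate_fluid"]
    )
    global_comparison["cell_richer_in_fluids"] = (
        global_comparison["cell_fluid"] > global_comparison["cell_sediment"]
    )
    return grouped, global_comparison


def threshold_counts(
    scores: pd.DataFrame,
    fraction_below: float = 0.50,
    photosynthate_share_above: float = 0.30,
) -> dict:
    """Narrative cut-off counts over a score table.

    Fractions are recomputed from the cell/photosynthate columns, so the
    counts are reproducible from the numbers rather than any printed
    rounding.
    """
    frac = necromass_fraction(scores["cell"], scores["photosynthate"])
    share = 1.0 - frac
    above = scores.loc[np.asarray(share) > photosynthate_share_above]
    stype = above["sample_type"].astype(str).str.lower()
    return {
        "n_fraction_below": int((np.asarray(frac) < fraction_below).sum()),
        "n_photosynthate_share_above": int(len(above)),
        "n_photosynthate_share_above_sediment": int(stype.str.startswith("s").sum()),
    }
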