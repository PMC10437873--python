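"""Synthetic study generator with planted ground truth.

Emulates the file set of a multi-province geothermal-spring metagenome
survey — site metadata, dbcan-style CAZyme overview tables, DRAM-style
MEROPS/EC annotation tables, SignalP-style secretion summaries, prokka
GFF3 gene maps, per-contig coverage tables and assembly statistics — with
known planted structure:

- a target cell-vs-photosynthate composition of the substrate-group-mapped
  secreted CAZymes (the quantity the necromass fraction estimates),
- enrichment of cellulose-degrading families in volcanic provinces,
- depauperation of annotations in very hot (> 80 degC) springs.

Only annotation-level tables are generated; no reads or sequences.

Family pools used for the planted cell/photosynthate draw contain only
families exclusive to one supergroup: GH5, GH7 and GH8 sit in both chitin
and xylan/cellulose in the substrate map, so drawing them would add equal
mass to both supergroups and make the planted fraction unidentifiable.
The shared-family and multi-group code paths are exercised by constructed
matrices in the test-suite instead.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from thermenz.abundance import NORMALIZATION_SCALE
from thermenz.assays import AssayPlate, Calibration, SlurrySpec, sediment_mass_per_well


class ConfigError(ValueError):
    """An invalid simulation-config field, named in the message."""


PROVINCES = (
    "Costa Rica outer forearc",
    "Costa Rica active volcanic arc",
    "Costa Rica backarc",
    "Cordillera Talamanca",
    "Panama slab window",
    "Argentina backarc",
    "Iceland spreading center",
)

#: provinces with direct magmatic influence (volcanic arcs/backarcs, hot spot)
VOLCANIC_PROVINCES = frozenset({
    "Costa Rica active volcanic arc",
    "Costa Rica backarc",
    "Argentina backarc",
    "Iceland spreading center",
})

_DEFAULT_PROVINCE_PROBS = {
    "Costa Rica outer forearc": 0.16,
    "Costa Rica active volcanic arc": 0.27,
    "Costa Rica backarc": 0.08,
    "Cordillera Talamanca": 0.19,
    "Panama slab window": 0.14,
    "Argentina backarc": 0.13,
    "Iceland spreading center": 0.03,
}

# temperature (degC) and pH intervals per province, spanning the observed
# extremes of the surveyed springs
_DEFAULT_TEMP_RANGES = {
    "Costa Rica outer forearc": (26.4, 48.7),
    "Costa Rica active volcanic arc": (19.2, 88.9),
    "Costa Rica backarc": (28.7, 35.0),
    "Cordillera Talamanca": (26.0, 60.0),
    "Panama slab window": (26.3, 50.9),
    "Argentina backarc": (27.8, 84.0),
    "Iceland spreading center": (25.7, 93.5),
}
_DEFAULT_PH_RANGES = {
    "Costa Rica outer forearc": (7.1, 10.0),
    "Costa Rica active volcanic arc": (0.8, 6.3),
    "Costa Rica backarc": (5.8, 9.5),
    "Cordillera Talamanca": (6.5, 9.1),
    "Panama slab window": (7.0, 10.0),
    "Argentina backarc": (3.2, 9.1),
    "Iceland spreading center": (1.8, 2.7),
}

# supergroup-exclusive CAZy family pools (see module docstring)
_CELL_FAMILIES = (
    "GH18", "GH19", "GH20", "GH46", "CBM5",                       # chitin
    "GH22", "GH23", "GH24", "GH25", "GH102", "GH103", "GH108",    # peptidoglycan
    "CBM50", "CE4",
)
_PHOTO_FAMILIES = (
    "GH3", "GH10", "GH11", "GH43", "GH67",                        # xylan side
    "GH1", "GH9", "GH16", "GH51", "GH74", "GH116",                # cellulose side
)
_CELLULOSE_FAMILIES = frozenset(
    {"GH1", "GH3", "GH9", "GH10", "GH16", "GH43", "GH51", "GH74", "GH116"}
)
_BACKGROUND_CAZY = (
    # starch/glycogen and trehalose families (grouped, but in neither supergroup)
    "GH13", "GH14", "GH15", "GH27", "GH31", "GH38", "GH57", "GH72", "GH77",
    "GH89", "GH119", "GH126", "AA13", "GT35", "CBM20", "GH37", "GH65",
    # ungrouped background families
    "GH2", "GH4", "GH26", "GH29", "GH33", "GH78", "GH92", "GH109", "GH130",
    "GH140", "GT2", "GT4", "GT41", "CBM13", "CBM32", "CBM48", "PL1", "PL9",
    "CE1", "AA3",
)
_MEROPS_POOL = (
    "S11", "M23", "S13", "S66", "M15", "M74", "M14", "C51",       # peptidoglycan
    "S09", "C26", "S33", "M38", "C44", "S49", "M20", "M50", "S16",
    "M01", "C01", "S01", "A01", "M16", "M24", "S08", "T01", "U32",
    "N04", "G01",
)
_EC_POOL = (
    "3.4.21.107", "3.5.1.28", "3.4.21.62", "3.4.21.102", "3.4.21.26",
    "3.1.1.3", "3.5.2.6", "3.1.3.1", "3.2.1.21", "3.2.1.51", "3.4.14.5",
    "3.6.1.1", "2.7.1.1", "1.1.1.1", "5.3.1.9", "4.2.1.2",
)

_SUBFAMILY_FAMILIES = frozenset({"GH13", "GH43"})  # written as GH13_20 etc.


def _default_pools() -> dict:
    return {
        "cazy_cell": list(_CELL_FAMILIES),
        "cazy_photo": list(_PHOTO_FAMILIES),
        "cazy_background": list(_BACKGROUND_CAZY),
        "merops": list(_MEROPS_POOL),
        "ec": list(_EC_POOL),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults emulate a scaled-down survey."""

    n_sites: int = 16
    provinces: dict = field(default_factory=lambda: dict(_DEFAULT_PROVINCE_PROBS))
    temp_range_by_province: dict = field(default_factory=lambda: dict(_DEFAULT_TEMP_RANGES))
    ph_range_by_province: dict = field(default_factory=lambda: dict(_DEFAULT_PH_RANGES))
    frac_fluid: float = 0.5
    n_contigs_per_sample: int = 400
    contig_length_dist: tuple = (8.0, 1.0)   # log-normal mu, sigma of bp
    genes_per_contig: float = 3.0            # Poisson mean
    scheme_family_pools: dict = field(default_factory=_default_pools)
    scheme_probs: dict = field(default_factory=lambda: {"CAZY": 0.45, "MEROPS": 0.40, "EC": 0.15})
    group_gene_prob: float = 0.5             # CAZY genes drawn from the planted mechanism
    cell_vs_photo_ratio: float = 0.70
    volcanic_cellulose_enrichment: float = 3.0
    volcanic_provinces: frozenset = VOLCANIC_PROVINCES
    hightemp_depauperation: float = 0.1
    hightemp_threshold: float = 80.0         # degC
    secreted_prob: float = 0.35
    two_tool_prob: float = 0.8
    depth_dist: tuple = (2.0, 15.0)          # gamma shape, scale of contig depth
    seed: int = 0

    def validate(self) -> None:
        def prob(name):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

        if self.n_sites < 1:
            raise ConfigError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in ("frac_fluid", "cell_vs_photo_ratio", "secreted_prob",
                     "two_tool_prob", "group_gene_prob"):
            prob(name)
        if not 0.0 < self.hightemp_depauperation <= 1.0:
            raise ConfigError(
                f"hightemp_depauperation must be in (0, 1], got {self.hightemp_depauperation}"
            )
        if self.volcanic_cellulose_enrichment < 1.0:
            raise ConfigError(
                f"volcanic_cellulose_enrichment must be >= 1, "
                f"got {self.volcanic_cellulose_enrichment}"
            )
        if abs(sum(self.provinces.values()) - 1.0) > 1e-9:
            raise ConfigError("provinces probabilities must sum to 1")
        if abs(sum(self.scheme_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("scheme_probs must sum to 1")
        for p in self.provinces:
            if p not in self.temp_range_by_province:
                raise ConfigError(f"temp_range_by_province missing province {p!r}")
            if p not in self.ph_range_by_province:
                raise ConfigError(f"ph_range_by_province missing province {p!r}")
        if self.n_contigs_per_sample < 1:
            raise ConfigError("n_contigs_per_sample must be >= 1")
        if self.genes_per_contig <= 0:
            raise ConfigError("genes_per_contig must be > 0")
        if any(v <= 0 for v in self.depth_dist):
            raise ConfigError("depth_dist parameters must be > 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class PlantedTruth:
    """Generator-side bookkeeping of what the pipeline should recover.

    ``group_abundance`` holds, per sample, the normalised cell and
    photosynthate sums accumulated gene-by-gene during generation over
    exactly the genes that pass the default filters (secreted, two-tool);
    ``necromass_fraction`` is their per-sample ratio. ``photo_weights``
    records the per-province sampling weights over photosynthate families.
    """

    group_abundance: pd.DataFrame          # sample x {cell, photosynthate}
    necromass_fraction: pd.Series
    sample_province: pd.Series
    sample_temperature: pd.Series
    photo_weights: dict

    @property
    def study_fraction(self) -> float:
        cell = float(self.group_abundance["cell"].sum())
        photo = float(self.group_abundance["photosynthate"].sum())
        return cell / (cell + photo)


@dataclass
class StudySet:
    """Paths of one generated synthetic study."""

    root: Path
    metadata: Path
    assembly_stats: Path
    samples: list[str]

    def sample_file(self, sample: str, kind: str) -> Path:
        names = {"cazy": "cazy_overview.tsv", "dram": "annotations.tsv",
                 "signalp": "signalp.tsv", "gff": "genes.gff",
                 "coverage": "coverage.tsv"}
        return self.root / sample / names[kind]


def _choice(rng: np.random.Generator, items: list, weights=None) -> str:
    if weights is None:
        return items[rng.integers(len(items))]
    w = np.asarray(weights, dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def generate_study(config: SimulationConfig, outdir) -> tuple[StudySet, PlantedTruth]:
    """Write a complete synthetic study under ``outdir``.

    Identical config (including seed) produces byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)

    pools = config.scheme_family_pools
    prov_labels = list(config.provinces)
    prov_probs = np.array([config.provinces[p] for p in prov_labels], dtype=float)
    scheme_labels = list(config.scheme_probs)
    scheme_probs = np.array([config.scheme_probs[s] for s in scheme_labels], dtype=float)

    photo = pools["cazy_photo"]
    photo_weights = {}
    for prov in prov_labels:
        w = np.ones(len(photo))
        if prov in config.volcanic_provinces:
            for i, fam in enumerate(photo):
                if fam in _CELLULOSE_FAMILIES:
                    w[i] *= config.volcanic_cellulose_enrichment
        photo_weights[prov] = w / w.sum()

    meta_rows = []
    stats_rows = []
    samples = []
    truth_rows = []

    for i in range(config.n_sites):
        province = _choice(rng, prov_labels, prov_probs)
        tlo, thi = config.temp_range_by_province[province]
        plo, phi = config.ph_range_by_province[province]
        temperature = float(rng.uniform(tlo, thi))
        ph = float(rng.uniform(plo, phi))
        fluid = rng.random() < config.frac_fluid
        sample = f"SY{i + 1:02d}{'F' if fluid else 'S'}"
        samples.append(sample)
        sdir = root / sample
        sdir.mkdir(exist_ok=True)

        mu, sigma = config.contig_length_dist
        lengths = np.maximum(rng.lognormal(mu, sigma, config.n_contigs_per_sample), 500.0)
        lengths = lengths.astype(np.int64)
        shape, scale = config.depth_dist
        depths = np.round(rng.gamma(shape, scale, config.n_contigs_per_sample), 4)
        total_length = int(lengths.sum())
        norm = NORMALIZATION_SCALE / total_length

        keep_prob = (config.hightemp_depauperation
                     if temperature > config.hightemp_threshold else 1.0)

        cazy_rows = []
        dram_rows = []
        sp_rows = []
        gff_rows = []
        cov_rows = []
        cell_sum = 0.0
        photo_sum = 0.0

        for c in range(config.n_contigs_per_sample):
            contig = f"{sample}_c{c + 1:05d}"
            length = int(lengths[c])
            depth = float(depths[c])
            cov_rows.append(f"{contig}\t{depth:.4f}\t{length}\n")
            n_genes = rng.poisson(config.genes_per_contig)
            for g in range(n_genes):
                # the keep decision is applied after all draws so that the
                # random stream is identical across depauperation settings:
                # lowering keep_prob removes genes, never reshuffles them
                keep = rng.random() < keep_prob
                gene = f"{contig}_{g + 1:05d}"
                start = int((g * 97) % max(length - 100, 1)) + 1
                if keep:
                    gff_rows.append(
                        f"{contig}\tsynth\tCDS\t{start}\t{start + 89}\t.\t+\t0\tID={gene}\n"
                    )
                secreted = rng.random() < config.secreted_prob
                if keep:
                    sp_rows.append(
                        f"{gene}\t{'SP(Sec/SPI)' if secreted else 'OTHER'}\n"
                    )
                scheme = _choice(rng, scheme_labels, scheme_probs)
                if scheme == "CAZY":
                    grouped = rng.random() < config.group_gene_prob
                    if grouped:
                        if rng.random() < config.cell_vs_photo_ratio:
                            fam, side = _choice(rng, pools["cazy_cell"]), "cell"
                        else:
                            fam = _choice(rng, photo, photo_weights[province])
                            side = "photo"
                    else:
                        fam, side = _choice(rng, pools["cazy_background"]), None
                    two_tools = rng.random() < config.two_tool_prob
                    hmmer_label = fam
                    if fam in _SUBFAMILY_FAMILIES and rng.random() < 0.3:
                        hmmer_label = f"{fam}_{rng.integers(1, 40)}"
                    lo = rng.integers(1, 60)
                    hmmer_cell = f"{hmmer_label}({lo}-{lo + 250})"
                    if two_tools:
                        row = f"{gene}\t{hmmer_cell}\t{fam}\t2\n"
                    elif rng.random() < 0.5:
                        row = f"{gene}\t{hmmer_cell}\t-\t1\n"
                    else:
                        row = f"{gene}\t-\t{fam}\t1\n"
                    if keep:
                        cazy_rows.append(row)
                        if secreted and two_tools and side is not None:
                            if side == "cell":
                                cell_sum += depth * norm
                            else:
                                photo_sum += depth * norm
                elif scheme == "MEROPS":
                    fam = _choice(rng, pools["merops"])
                    if keep:
                        dram_rows.append(f"{gene}\t{contig}\t{fam}\t\n")
                else:
                    ec = _choice(rng, pools["ec"])
                    if keep:
                        dram_rows.append(f"{gene}\t{contig}\t\t{ec}\n")

        with open(sdir / "cazy_overview.tsv", "w") as fh:
            fh.write("Gene ID\tHMMER\tDIAMOND\t#ofTools\n")
            fh.writelines(cazy_rows)
        with open(sdir / "annotations.tsv", "w") as fh:
            fh.write("gene_id\tscaffold\tpeptidase_family\tec_number\n")
            fh.writelines(dram_rows)
        with open(sdir / "signalp.tsv", "w") as fh:
            fh.write("gene_id\tPrediction\n")
            fh.writelines(sp_rows)
        with open(sdir / "genes.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.writelines(gff_rows)
        with open(sdir / "coverage.tsv", "w") as fh:
            fh.write("contig_id\tmean_depth\tlength\n")
            fh.writelines(cov_rows)

        meta_rows.append(
            f"{sample}\t{sample}\tSynthetic spring {i + 1}\tSynthetica\t"
            f"{rng.uniform(-30, 65):.6f}\t{rng.uniform(-90, -20):.6f}\t"
            f"{province}\t{temperature:.1f}\t{ph:.2f}\n"
        )
        stats_rows.append(f"{sample}\t{total_length}\t{config.n_contigs_per_sample}\n")
        truth_rows.append({
            "sample": sample, "cell": cell_sum, "photosynthate": photo_sum,
            "province": province, "temperature": temperature,
        })

    meta_path = root / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("abbrev\tsample_name\tsite_name\tregion\tlatitude\tlongitude\t"
                 "province\ttemperature\tpH\n")
        fh.writelines(meta_rows)
    stats_path = root / "assembly_stats.tsv"
    with open(stats_path, "w") as fh:
        fh.write("sample_id\ttotal_length\tn_contigs\n")
        fh.writelines(stats_rows)

    tdf = pd.DataFrame(truth_rows).set_index("sample")
    denom = tdf["cell"] + tdf["photosynthate"]
    frac = tdf["cell"] / denom.where(denom > 0)
    truth = PlantedTruth(
        group_abundance=tdf[["cell", "photosynthate"]],
        necromass_fraction=frac,
        sample_province=tdf["province"],
        sample_temperature=tdf["temperature"],
        photo_weights={p: dict(zip(photo, w)) for p, w in photo_weights.items()},
    )
    return StudySet(root=root, metadata=meta_path, assembly_stats=stats_path,
                    samples=samples), truth


def generate_assay_plate(
    true_rates: dict[str, float],
    calibration: Calibration,
    noise_sd: float,
    seed: int,
    spec: SlurrySpec = SlurrySpec(),
    sample_id: str = "SY01S",
    timepoints: tuple[float, ...] = (0.0, 1.5, 3.0),
    n_replicates: int = 2,
) -> list[AssayPlate]:
    """Simulate fluorometric plates whose expected readings rise linearly
    at the fluorescence rate implied by each substrate's true hydrolysis
    rate (umol/g_wet/h), the slurry bookkeeping and the standard curve.

    Returns one plate per substrate in ``true_rates``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    for sub, r in true_rates.items():
        if r < 0:
            raise ValueError(f"true rate for {sub} must be >= 0, got {r}")
    rng = np.random.default_rng(seed)
    mass = sediment_mass_per_well(spec)
    vol_l = spec.well_volume_ml / 1000.0
    t = np.asarray(timepoints, dtype=float)

    plates = []
    for sub in sorted(true_rates):
        conc_rate = true_rates[sub] * mass / vol_l       # uM per hour
        expected = calibration.intercept + calibration.slope * conc_rate * t
        fl = np.tile(expected, (n_replicates, 1))
        if noise_sd > 0:
            fl = fl + rng.normal(0.0, noise_sd, fl.shape)
        fl = np.maximum(fl, 0.0)  # fluorimeter floor
        plates.append(AssayPlate(sample_id=sample_id, substrate=sub,
                                 timepoints=tuple(t), fluorescence=fl))
    return plates


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
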