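"""Fluorometric extracellular enzyme assays on sediment slurries.

2.75 g wet sediment is blended into 91 mL of buffer; 800 uL of slurry plus
200 uL of 200 uM fluorogenic substrate (MUB- or AMC-linked) go into each
well, in duplicate. Fluorescence is read at 0, 1.5 and 3 h. The hydrolysis
rate per well is the least-squares slope of fluorescence against time,
converted to concentration via a standard-curve slope (fluorescence units
per uM of free fluorophore), to moles via the well volume, and to a
mass-specific potential rate (umol per g wet sediment per hour) via the
sediment mass carried into the well by the slurry aliquot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from thermenz.io import sample_type_from_id
from thermenz.stats import KruskalResult, kruskal_wallis

#: substrate codes: alpha-glucosidase, beta-glucosidase, cellobiohydrolase,
#: N-acetyl-beta-D-glucosaminidase, leucine aminopeptidase, phosphatase,
#: sulfatase, xylosidase
SUBSTRATES = ("AG", "BG", "CB", "NAG", "LEU", "PHOS", "SULF", "XYL")


@dataclass(frozen=True)
class SlurrySpec:
    """Slurry and well bookkeeping; defaults follow the field protocol."""

    sediment_mass: float = 2.75      # g wet
    buffer_volume: float = 91.0      # mL
    aliquot_volume: float = 0.8      # mL slurry per well
    substrate_volume: float = 0.2    # mL substrate solution per well
    substrate_stock: float = 200.0   # uM

    def __post_init__(self) -> None:
        for name in ("sediment_mass", "buffer_volume", "aliquot_volume",
                     "substrate_volume", "substrate_stock"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def well_volume_ml(self) -> float:
        return self.aliquot_volume + self.substrate_volume


@dataclass(frozen=True)
class Calibration:
    """Standard curve: fluorescence = slope * [fluorophore uM] + intercept."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


@dataclass
class AssayPlate:
    """Fluorescence time series for one sample x substrate, with duplicates.

    ``fluorescence`` is (n_replicates, n_timepoints) in arbitrary units.
    """

    sample_id: str
    substrate: str
    timepoints: tuple[float, ...]
    fluorescence: np.ndarray
    incubation_temperature: float | None = None
    buffer_pH: float | None = None

    def __post_init__(self) -> None:
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.fluorescence.shape[1] != len(self.timepoints):
            raise ValueError("fluorescence columns must match timepoints")
        if (self.fluorescence < 0).any():
            raise ValueError("negative fluorescence reading")


@dataclass
class RateResult:
    sample_id: str
    substrate: str
    rate: float                  # umol / g_wet / h, duplicates averaged
    per_replicate: list[float]


def sediment_mass_per_well(spec: SlurrySpec = SlurrySpec()) -> float:
    """Wet sediment mass (g) carried into one well by the slurry aliquot.

    The sediment's own volume contribution to the slurry is neglected.
    """
    return spec.sediment_mass * spec.aliquot_volume / spec.buffer_volume


def hydrolysis_rate(
    plate: AssayPlate,
    cal: Calibration,
    spec: SlurrySpec = SlurrySpec(),
    blank: np.ndarray | None = None,
    allow_fluids: bool = False,
) -> RateResult:
    """Potential hydrolysis rate in umol per g wet sediment per hour.

    Per replicate: OLS slope of fluorescence vs time (FU/h), divided by
    the calibration slope (-> uM/h), times the well volume in litres
    (-> umol/h), divided by the sediment mass per well. Negative rates are
    reported as-is. ``blank`` (same shape as the fluorescence block, or
    one row per timepoint) is subtracted before regression when provided.

    Assays are a sediment protocol; fluid samples are refused unless
    ``allow_fluids`` is set.
    """
    if not allow_fluids and sample_type_from_id(plate.sample_id) == "fluid":
        raise ValueError(
            f"sample {plate.sample_id!r} is a fluid; the slurry assay is "
            "defined for sediments (pass allow_fluids=True to override)"
        )
    fl = plate.fluorescence.astype(float)
    if blank is not None:
        fl = fl - np.atleast_2d(np.asarray(blank, dtype=float))
    t = np.asarray(plate.timepoints, dtype=float)
    mass = sediment_mass_per_well(spec)
    vol_l = spec.well_volume_ml / 1000.0

    per_rep = []
    for row in fl:
        slope_fu = np.polyfit(t, row, 1)[0]          # FU / h
        conc_rate = slope_fu / cal.slope             # uM / h
        per_rep.append(conc_rate * vol_l / mass)     # umol / g / h
    return RateResult(plate.sample_id, plate.substrate,
                      float(np.mean(per_rep)), [float(r) for r in per_rep])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_plate_long(path) -> list[AssayPlate]:
    """Long-format plate TSV: sample, substrate, replicate, hour, fluorescence."""
    df = pd.read_csv(path, sep="\t")
    plates = []
    for (sample, substrate), grp in df.groupby(["sample", "substrate"], sort=False):
        wide = grp.pivot_table(index="replicate", columns="hour",
                               values="fluorescence", sort=True)
        plates.append(AssayPlate(
            sample_id=str(sample), substrate=str(substrate),
            timepoints=tuple(float(h) for h in wide.columns),
            fluorescence=wide.to_numpy(),
        ))
    return plates


def write_plate_long(plates: list[AssayPlate], path) -> None:
    rows = []
    for p in plates:
        for rep, series in enumerate(p.fluorescence):
            for hour, fu in zip(p.timepoints, series):
                rows.append({"sample": p.sample_id, "substrate": p.substrate,
                             "replicate": rep, "hour": hour,
                             "fluorescence": repr(float(fu))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calibration(path) -> Calibration:
    """Fit a standard curve from a TSV of (standard_uM, fluorescence)."""
    df = pd.read_csv(path, sep="\t")
    slope, intercept = np.polyfit(df.iloc[:, 0], df.iloc[:, 1], 1)
    return Calibration(slope=float(slope), intercept=float(intercept))


def province_comparison(
    rates: pd.DataFrame,
    provinces: dict[str, str],
) -> dict[str, KruskalResult]:
    """Kruskal-Wallis test of rates across provinces, one per substrate.

    ``rates`` has columns sample_id, substrate, rate; ``provinces`` maps
    sample id -> province label.
    """
    out: dict[str, KruskalResult] = {}
    for substrate, grp in rates.groupby("substrate", sort=True):
        labels = grp["sample_id"].map(provinces)
        if labels.isna().any():
            missing = grp.loc[labels.isna(), "sample_id"].tolist()
            raise KeyError(f"samples missing province metadata: {missing}")
        if labels.nunique() < 2:
            raise ValueError(
                f"substrate {substrate}: need at least two provinces with data"
            )
        out[str(substrate)] = kruskal_wallis(grp["rate"].to_numpy(),
                                             labels.to_numpy(), label=str(substrate))
    return out
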