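"""Per-class phenology profiles and scene configuration.

A :class:`PhenologyProfile` describes one land-use class by its seasonal NDVI
trajectory (a double-logistic greenness curve over the agronomic year) plus the
spectral rules that turn NDVI into a 12-band surface-reflectance vector.  Days
are counted from the start of the agronomic year (day 0 = September 1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

#: Sentinel-2 band order used throughout (all L2A bands except B10).
BAND_NAMES: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8a", "B9", "B11", "B12",
)

#: Bands whose values are affine functions of NDVI when listed as informative.
#: B4 and B8 are handled separately (they *define* NDVI) and are always coupled
#: to the phenology curve.  B1 (aerosols) and B9 (water vapour) default to
#: class-independent atmospheric constants.
_AFFINE_TEMPLATES: dict[str, tuple[float, float]] = {
    # band: (intercept, slope against NDVI)
    "B1": (0.12, 0.0),
    "B2": (0.08, -0.04),
    "B3": (0.10, -0.03),
    "B5": (0.15, 0.10),
    "B6": (0.18, 0.22),
    "B7": (0.20, 0.26),
    "B8a": (0.22, 0.28),
    "B9": (0.10, 0.0),
    "B11": (0.25, -0.12),
    "B12": (0.20, -0.10),
}


@dataclass
class PhenologyProfile:
    """Seasonal NDVI trajectory and spectral rules for one land-use class.

    Parameters
    ----------
    class_name
        Short class label (e.g. ``"RIC"`` for rice).
    ndvi_base
        NDVI baseline outside the growing season, in ``[-0.2, 0.3]``.
    ndvi_amplitude
        Peak seasonal NDVI excursion above the baseline, in ``[0, 0.8]``.
    greenup_day, senescence_day
        Inflection days of the green-up and senescence logistics, counted
        from September 1 (day 0) of the agronomic year.
    greenup_rate, senescence_rate
        Logistic slopes in 1/day; larger is steeper.
    band_noise_sd
        Standard deviation of i.i.d. Gaussian reflectance noise per
        pixel/date/band.
    informative_bands
        Subset of :data:`BAND_NAMES` (besides B4/B8, which always carry the
        NDVI signal) whose values depend on NDVI with class-specific affine
        coefficients; the remaining bands receive class-independent values.
    band_sum
        B4 + B8 total reflectance used to solve the two NDVI-carrying bands.
    """

    class_name: str
    ndvi_base: float
    ndvi_amplitude: float
    greenup_day: float
    senescence_day: float
    greenup_rate: float = 0.1
    senescence_rate: float = 0.1
    band_noise_sd: float = 0.02
    informative_bands: frozenset[str] = frozenset(
        b for b in BAND_NAMES if b not in ("B1", "B9")
    )
    band_sum: float = 0.5
    band_affine: dict[str, tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not -0.2 <= self.ndvi_base <= 0.3:
            raise ValueError(f"ndvi_base {self.ndvi_base} outside [-0.2, 0.3]")
        if not 0.0 <= self.ndvi_amplitude <= 0.8:
            raise ValueError(f"ndvi_amplitude {self.ndvi_amplitude} outside [0, 0.8]")
        if self.ndvi_base + self.ndvi_amplitude > 1.0:
            raise ValueError("ndvi_base + ndvi_amplitude must not exceed 1.0")
        if not self.greenup_day < self.senescence_day:
            raise ValueError("greenup_day must precede senescence_day")
        if self.greenup_rate <= 0 or self.senescence_rate <= 0:
            raise ValueError("logistic rates must be positive")
        unknown = set(self.informative_bands) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in informative_bands: {sorted(unknown)}")
        self.informative_bands = frozenset(self.informative_bands)
        if self.band_affine is None:
            self.band_affine = self._default_affine()

    def _default_affine(self) -> dict[str, tuple[float, float]]:
        # Class-specific jitter derived from a stable hash of the class name,
        # so two profiles with different names have distinct spectral slopes.
        rng = np.random.default_rng(zlib.crc32(self.class_name.encode()))
        out: dict[str, tuple[float, float]] = {}
        for band, (icpt, slope) in _AFFINE_TEMPLATES.items():
            if band in self.informative_bands:
                out[band] = (
                    icpt + float(rng.uniform(-0.02, 0.02)),
                    slope + float(rng.uniform(-0.05, 0.05)),
                )
            else:
                # class-independent: template intercept, no NDVI dependence
                out[band] = (icpt, 0.0)
        return out


def default_profiles() -> list[PhenologyProfile]:
    """The default 16-class profile set.

    Annual crops get pronounced seasonal cycles — rice (RIC) and sunflower
    (SUN) peak in summer, winter cereals (BAR, OAT, WHE, TRI) in
    winter–spring — while permanent crops and natural vegetation (forest,
    pastures, shrubs, citrus, olive, ...) get flatter, mutually similar
    trajectories, which is what makes them harder to tell apart.
    """
    p = PhenologyProfile
    return [
        # annual crops
        p("RIC", 0.08, 0.72, 255, 350, 0.15, 0.15),
        p("SUN", 0.12, 0.55, 240, 330, 0.12, 0.12),
        p("VIN", 0.18, 0.35, 220, 345, 0.08, 0.08),
        p("BAR", 0.15, 0.55, 95, 255, 0.10, 0.10),
        p("OAT", 0.15, 0.50, 105, 265, 0.10, 0.10),
        p("WHE", 0.15, 0.58, 110, 275, 0.10, 0.10),
        p("TRI", 0.15, 0.52, 100, 270, 0.10, 0.10),
        p("FAL", 0.20, 0.15, 120, 230, 0.06, 0.06),
        # permanent crops and natural vegetation
        p("FOR", 0.30, 0.10, 150, 330, 0.05, 0.05, band_sum=0.55),
        p("TRE", 0.28, 0.12, 140, 320, 0.05, 0.05, band_sum=0.52),
        p("SHR", 0.24, 0.14, 130, 310, 0.06, 0.06),
        p("PAS", 0.20, 0.22, 120, 250, 0.08, 0.08),
        p("DFR", 0.18, 0.16, 160, 320, 0.06, 0.06, band_sum=0.45),
        p("CIT", 0.30, 0.08, 170, 340, 0.05, 0.05, band_sum=0.6),
        p("OLI", 0.22, 0.09, 150, 330, 0.05, 0.05, band_sum=0.42),
        p("FRU", 0.25, 0.20, 180, 320, 0.07, 0.07, band_sum=0.48),
    ]


#: Reference class frequencies (fractions of pixels) mirroring an in-situ
#: survey's heavily imbalanced class distribution; used as the default
#: class_proportions for the 16-class profile set.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "TRE": 663995, "FOR": 495223, "VIN": 240418, "RIC": 230935,
    "SHR": 165110, "DFR": 153727, "CIT": 125161, "FAL": 84491,
    "BAR": 71623, "OLI": 49829, "PAS": 33408, "FRU": 29859,
    "OAT": 28754, "WHE": 11437, "SUN": 10104, "TRI": 4252,
}


def default_proportions(profiles: list[PhenologyProfile]) -> np.ndarray:
    """Class proportions for *profiles*: survey frequencies where the class
    name is known, otherwise uniform over the unknown classes."""
    counts = np.array(
        [DEFAULT_CLASS_COUNTS.get(pr.class_name, 0) for pr in profiles], float
    )
    if counts.sum() == 0:
        counts[:] = 1.0
    elif (counts == 0).any():
        counts[counts == 0] = counts[counts > 0].mean()
    return counts / counts.sum()


@dataclass
class SceneConfig:
    """Configuration of one synthetic labeled scene.

    ``date_list`` holds agronomic-year day numbers (0 = September 1); the
    default is 30 dates evenly spaced over one September→August year.
    """

    grid_height: int = 96
    grid_width: int = 96
    parcel_size: int = 8
    profiles: list[PhenologyProfile] = None  # type: ignore[assignment]
    class_proportions: np.ndarray = None  # type: ignore[assignment]
    n_dates: int = 30
    date_list: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profiles is None:
            self.profiles = default_profiles()
        if self.class_proportions is None:
            self.class_proportions = default_proportions(self.profiles)
        self.class_proportions = np.asarray(self.class_proportions, float)
        if self.date_list is None:
            self.date_list = np.linspace(0.0, 364.0, self.n_dates)
        self.date_list = np.asarray(self.date_list, float)
        if self.n_dates != len(self.date_list):
            raise ValueError("n_dates must equal len(date_list)")
        if len(self.class_proportions) != len(self.profiles):
            raise ValueError("class_proportions length must match profiles")
        if abs(self.class_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")

    @property
    def class_names(self) -> list[str]:
        return [p.class_name for p in self.profiles]
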