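"""Configuration objects for the scene generator and the pipeline.

``SimConfig`` defines the synthetic study conditions (grid, record span,
seasonal cycle, noise, fire events, climate anomalies).  ``RunConfig``
bundles a ``SimConfig`` with every stage parameter of the analysis chain;
its defaults are the reference values of the method (7-day burn-date
uncertainty cut, 4-year recurrence gap, 2-5-year fit windows, adjusted-r2
screen at 0.25, 25th-75th IQR group selection, 0.01/0.99 regression
quantiles, 3 pre-fire months).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .containers import LANDCOVER_CATEGORIES
from .errors import ConfigError


@dataclass
class SimConfig:
    grid_rows: int = 20
    grid_cols: int = 20
    start_year: int = 2001
    end_year: int = 2022
    cadence_days: int = 16
    seasonal_amplitude: float = 0.12   # EVI units
    seasonal_mean: float = 0.65        # EVI units
    trend_slope: float = 0.0           # EVI per year
    noise_sd: float = 0.02             # EVI units, per composite
    ar1_coeff: float = 0.3             # lag-1 autocorrelation of the noise
    cloud_fraction: float = 0.05       # share of low-quality observations
    events_per_pixel: int = 2
    a_true_range: tuple[float, float] = (-0.5, -0.2)   # drop depth, EVI units
    b_true_range: tuple[float, float] = (0.03, 0.12)   # month^-1
    event_gap_range: tuple[int, int] = (48, 84)        # months between fires
    burn_uncertainty_range: tuple[int, int] = (0, 7)   # days
    landcover_categories: tuple[str, ...] = ("BL", "NL", "Shb", "TW")
    hemisphere: str = "north"
    fire_season_months: tuple[int, ...] | None = None  # default per hemisphere
    climate_cell_size: int = 4         # pixels per climate cell, per axis
    climate_anomaly_spec: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.end_year <= self.start_year:
            raise ConfigError("end_year", "must exceed start_year")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigError("grid_rows", "grid must be at least 1x1")
        lo = self.seasonal_mean - self.seasonal_amplitude
        hi = self.seasonal_mean + self.seasonal_amplitude
        if lo < 0 or hi > 1:
            raise ConfigError(
                "seasonal_mean",
                f"seasonal_mean +/- seasonal_amplitude must stay in [0,1], got [{lo}, {hi}]",
            )
        if not (0 <= self.ar1_coeff < 1):
            raise ConfigError("ar1_coeff", "must be in [0, 1)")
        if not (0 <= self.cloud_fraction <= 1):
            raise ConfigError("cloud_fraction", "must be in [0, 1]")
        if self.events_per_pixel not in (0, 1, 2):
            raise ConfigError("events_per_pixel", "must be 0, 1 or 2")
        if not (0 < self.b_true_range[0] <= self.b_true_range[1] <= 1):
            raise ConfigError("b_true_range", "must lie within (0, 1]")
        if self.a_true_range[0] > self.a_true_range[1] or self.a_true_range[1] >= 0:
            raise ConfigError("a_true_range", "must be an ordered pair of negatives")
        if self.events_per_pixel == 2 and self.event_gap_range[0] < 48:
            raise ConfigError(
                "event_gap_range", "minimum gap must be >= 48 months for two events"
            )
        if self.hemisphere not in ("north", "south"):
            raise ConfigError("hemisphere", "must be 'north' or 'south'")
        for cat in self.landcover_categories:
            if cat not in LANDCOVER_CATEGORIES:
                raise ConfigError("landcover_categories", f"unknown category '{cat}'")
        for var, offsets in self.climate_anomaly_spec.items():
            if var not in ("precipitation", "temperature"):
                raise ConfigError("climate_anomaly_spec", f"unknown variable '{var}'")
            if len(offsets) != 4:
                raise ConfigError(
                    "climate_anomaly_spec", "expected 4 per-quarter z-offsets"
                )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        tup_fields = {
            "a_true_range", "b_true_range", "event_gap_range",
            "burn_uncertainty_range", "landcover_categories", "fire_season_months",
        }
        kw = {}
        for k, v in d.items():
            if k in tup_fields and v is not None:
                v = tuple(v)
            kw[k] = v
        return cls(**kw)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "run"
    # preprocessing
    keep_period_months: float = 3.0
    loess_span: float = 0.5
    apply_smoothing: bool = True
    apply_detrending: bool = True
    # fire history
    region: str = "mediterranean"
    max_uncertainty_days: float = 7.0
    min_gap_months: int = 48
    min_tail_months: int = 24
    # recovery fitting
    severity_search_months: int = 3
    fit_windows: tuple[int, ...] = (24, 36, 48, 60)
    r2_min: float = 0.25
    fit_intercept: bool = True
    se_method: str = "hc3"
    validity_rule: str = "both_valid"   # or "literal_both_fail"
    # modulation
    iqr_bounds: tuple[float, float] = (0.25, 0.75)
    taus: tuple[float, float] = (0.01, 0.99)
    n_bins: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (0.1 < self.loess_span <= 1):
            raise ConfigError("loess_span", "must be in (0.1, 1]")
        if self.validity_rule not in ("both_valid", "literal_both_fail"):
            raise ConfigError("validity_rule", "unknown rule")
        if self.se_method not in ("hc3", "classic"):
            raise ConfigError("se_method", "must be 'hc3' or 'classic'")
        if not (0 <= self.iqr_bounds[0] < self.iqr_bounds[1] <= 1):
            raise ConfigError("iqr_bounds", "must be an ordered pair in [0, 1]")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        for k, v in list(d["sim"].items()):
            if isinstance(v, tuple):
                d["sim"][k] = list(v)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = SimConfig.from_dict(d.pop("sim", {}))
        tup_fields = {"fit_windows", "iqr_bounds", "taus"}
        kw = {k: (tuple(v) if k in tup_fields else v) for k, v in d.items()}
        return cls(sim=sim, **kw)
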