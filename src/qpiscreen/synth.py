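"""Synthetic fixtures: plate layouts and single-cell mass-track generators.

The track generator emulates the salient statistics of imaging-derived
mass tracks: per-cell exponential growth with a normally distributed SGR,
an optional death phase (abrupt switch to exponential mass loss at a drawn
death time; the characteristic death rate is about -0.217 1/h),
multiplicative measurement noise on mass, and regular 20-min sampling over
72 h.  The dose-response generator places per-condition mean SGR on a
ground-truth Hill curve so end-to-end EC50 / DoR / ToR recovery can be
tested without any experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doseresponse import hill_curve

__all__ = [
    "PlateLayout",
    "SyntheticPopulationSpec",
    "generate_cell_tracks",
    "generate_dose_response_tracks",
    "dilution_series",
]


# --------------------------------------------------------------------------
# plate layout
# --------------------------------------------------------------------------

@dataclass
class WellCondition:
    drug: str
    concentration_uM: float
    solvent: str = "DMSO"
    cell_line: str = ""
    replicate_group: str = ""


@dataclass
class PlateLayout:
    """96-well plate map with ``locations_per_well`` imaging positions."""

    wells: dict[str, WellCondition]
    locations_per_well: int = 9

    def n_locations(self) -> int:
        return len(self.wells) * self.locations_per_well

    def locations(self) -> list[tuple[str, str]]:
        """(well, location_id) pairs, location ids '<well>_<i>'."""
        return [
            (w, f"{w}_{i}") for w in sorted(self.wells) for i in range(self.locations_per_well)
        ]

    def conditions(self) -> dict[tuple[str, float], list[str]]:
        """(drug, concentration) -> wells of that condition (replicates)."""
        out: dict[tuple[str, float], list[str]] = {}
        for w, c in sorted(self.wells.items()):
            out.setdefault((c.drug, c.concentration_uM), []).append(w)
        return out

    def locations_for_condition(self, drug: str, concentration_uM: float) -> list[str]:
        wells = self.conditions().get((drug, concentration_uM), [])
        return [f"{w}_{i}" for w in wells for i in range(self.locations_per_well)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        raw = yaml.safe_load(Path(path).read_text())
        wells = {
            w: WellCondition(
                drug=str(v["drug"]),
                concentration_uM=float(v.get("concentration_uM", 0.0)),
                solvent=str(v.get("solvent", "DMSO")),
                cell_line=str(v.get("cell_line", "")),
                replicate_group=str(v.get("replicate_group", "")),
            )
            for w, v in raw["wells"].items()
        }
        return cls(wells, int(raw.get("locations_per_well", 9)))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "locations_per_well": self.locations_per_well,
            "wells": {
                w: {
                    "drug": c.drug,
                    "concentration_uM": c.concentration_uM,
                    "solvent": c.solvent,
                    "cell_line": c.cell_line,
                    "replicate_group": c.replicate_group,
                }
                for w, c in self.wells.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def default_screen(
        cls,
        drugs: tuple[str, ...] = ("drugA", "drugB", "drugC", "drugD", "drugE"),
        concentrations_uM: tuple[float, ...] = (0.032, 0.16, 0.8, 4.0, 10.0, 20.0),
        n_replicates: int = 3,
        cell_line: str = "LINE1",
    ) -> "PlateLayout":
        """A 96-well screen: 5 drugs x 6 concentrations x 3 replicates plus
        triplicate DMSO and ethanol solvent controls (90 + 6 = 96 wells)."""
        rows = "ABCDEFGH"
        names = [f"{r}{c}" for r in rows for c in range(1, 13)]
        wells: dict[str, WellCondition] = {}
        i = 0
        for d in drugs:
            for conc in concentrations_uM:
                for rep in range(n_replicates):
                    wells[names[i]] = WellCondition(d, conc, "DMSO", cell_line, f"{d}_{conc}")
                    i += 1
        for solvent in ("DMSO", "ethanol"):
            for rep in range(n_replicates):
                wells[names[i]] = WellCondition(f"control_{solvent}", 0.0, solvent,
                                                cell_line, f"control_{solvent}")
                i += 1
        return cls(wells)


def dilution_series(stock_uM: float = 40.0, n_points: int = 6, factor: float = 2.0) -> list[float]:
    """Serial dilution: each step divides by ``factor``; the final 1:1
    addition of drugged media to cell media halves every concentration."""
    return [stock_uM / 2.0 / factor**k for k in range(n_points)]


# --------------------------------------------------------------------------
# track generator
# --------------------------------------------------------------------------

@dataclass
class SyntheticPopulationSpec:
    """Conditions for one synthetic cell population."""

    n_cells: int = 100
    sgr_mean_h: float = 0.02
    sgr_sd_h: float = 0.008
    death_fraction: float = 0.0
    death_time_range_h: tuple[float, float] = (6.0, 48.0)
    death_rate_h: float = -0.217
    frame_interval_min: float = 20.0
    duration_h: float = 72.0
    initial_mass_mean_pg: float = 300.0
    initial_mass_sd_pg: float = 80.0
    noise_cv: float = 0.01
    growth_model: str = "linear"  # "linear" (constant dm/dt) or "exponential"
    seed: int = 0
    well: str = "A1"
    location_id: str = "A1_0"

    def __post_init__(self) -> None:
        if not 0 <= self.death_fraction <= 1:
            raise ValueError("death fraction must lie in [0, 1]")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.growth_model not in ("linear", "exponential"):
            raise ValueError("growth model must be 'linear' or 'exponential'")


def generate_cell_tracks(spec: SyntheticPopulationSpec) -> pd.DataFrame:
    """Mass-versus-time tracks for one population (tracks.csv schema).

    Each cell accumulates mass at a constant rate set by its drawn SGR
    (dm/dt = SGR * m0, the constant-growth-rate picture of cells within a
    cell cycle, for which SGR = slope/intercept exactly), or exponentially
    when ``growth_model='exponential'``.  Dying cells switch at their drawn
    death time to mass loss at ``death_rate_h`` relative to the mass at
    death onset (floored at 5% of it).  Masses carry multiplicative
    Gaussian noise of CV ``noise_cv``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_min / 60.0
    times = np.arange(0.0, spec.duration_h + dt / 2, dt)
    sgr = rng.normal(spec.sgr_mean_h, spec.sgr_sd_h, spec.n_cells)
    m0 = np.clip(
        rng.normal(spec.initial_mass_mean_pg, spec.initial_mass_sd_pg, spec.n_cells),
        50.0, None,
    )
    dies = rng.random(spec.n_cells) < spec.death_fraction
    t_lo, t_hi = spec.death_time_range_h
    t_death = rng.uniform(t_lo, t_hi, spec.n_cells) if t_hi > t_lo else np.full(spec.n_cells, t_lo)
    x0 = rng.uniform(20, 1000, spec.n_cells)
    y0 = rng.uniform(20, 600, spec.n_cells)

    frames = []
    for i in range(spec.n_cells):
        if spec.growth_model == "linear":
            m = m0[i] * (1.0 + sgr[i] * times)
        else:
            m = m0[i] * np.exp(sgr[i] * times)
        if dies[i]:
            after = times >= t_death[i]
            j = int(np.argmax(after)) if after.any() else len(times)
            m_at = m[j] if j < len(times) else m[-1]
            decay = 1.0 + spec.death_rate_h * (times[after] - t_death[i])
            m[after] = m_at * np.clip(decay, 0.05, None)
        m = np.clip(m, 1.0, None)
        if spec.noise_cv > 0:
            m = m * (1.0 + spec.noise_cv * rng.standard_normal(len(times)))
        frames.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "well": spec.well,
                    "location": spec.location_id,
                    "frame": np.arange(len(times)),
                    "time_h": times,
                    "x": x0[i] + 0.5 * rng.standard_normal(len(times)).cumsum(),
                    "y": y0[i] + 0.5 * rng.standard_normal(len(times)).cumsum(),
                    "area_um2": m / 2.0,  # ~2 pg/um^2 areal density
                    "mass_pg": m,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_dose_response_tracks(
    e0: float,
    emax: float,
    ec50_uM: float,
    hs: float,
    layout: PlateLayout,
    n_cells_per_location: int = 12,
    sgr_sd_h: float = 0.008,
    sd_hill: tuple[float, float] | None = None,
    noise_cv: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Tracks for a whole plate with per-condition mean SGR on a Hill curve.

    Solvent-control wells (concentration 0) grow at ``e0``; per-cell SGRs
    are drawn around the condition mean (negative means yield decaying
    masses).  ``sd_hill`` optionally makes the per-cell SD
    concentration-dependent as (sd_low, sd_high) interpolated along the
    same Hill curve.
    """
    rng = np.random.default_rng(seed)
    out = []
    for well, cond in sorted(layout.wells.items()):
        c = cond.concentration_uM
        mu = e0 if c <= 0 else float(hill_curve(np.array([c]), e0, emax, ec50_uM, hs)[0])
        if sd_hill is not None:
            sd_lo, sd_hi = sd_hill
            frac = 0.0 if c <= 0 else 1.0 / (1.0 + (c / ec50_uM) ** (-hs))
            sd = sd_lo + (sd_hi - sd_lo) * frac
        else:
            sd = sgr_sd_h
        for i in range(layout.locations_per_well):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticPopulationSpec(
                n_cells=n_cells_per_location,
                sgr_mean_h=mu,
                sgr_sd_h=max(sd, 1e-5),
                noise_cv=noise_cv,
                seed=sub_seed,
                well=well,
                location_id=f"{well}_{i}",
            )
            out.append(generate_cell_tracks(spec))
    return pd.concat(out, ignore_index=True)
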