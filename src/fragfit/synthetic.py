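"""Synthetic capture-table generator for the three-landscape study design.

Generates site, species and capture tables with the statistical
structure the analysis assumes: three fragmented landscapes ordered by
remaining forest cover (by default 50, 30 and 10%, 17 surveyed patches
each with a shared log-uniform patch-size distribution), a paired
continuously forested control landscape with six sites per pair, two
sampling years, and per-site guild totals drawn from any one of the
eight candidate model structures.

Per-site guild totals are Poisson (or negative-binomial) around the
generating model's mean function; each total is then partitioned among
the guild's species multinomially according to a geometric
relative-abundance profile and split across the two years binomially
(p = 0.5).  The fitted models act on guild totals, so species-level and
temporal partitioning leave the modelled quantities' distributions
unchanged.

Presets encode the qualitative regimes the conceptual model predicts,
most notably ``regime_shift`` (model F: a positive patch-area effect
only in the intermediate landscape) and ``generalist_release`` (model
C with generalist means increasing as forest cover drops).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .candidate_models import CandidateModel, enumerate_candidates
from .data_model import Study
from .likelihood import mean_function

__all__ = [
    "Scenario",
    "preset_scenarios",
    "generate",
    "save_scenario",
    "load_scenario",
]

DEFAULT_COVERS = (50.0, 30.0, 10.0)
DEFAULT_N_PATCHES = 17
DEFAULT_AREA_RANGE = (2.0, 300.0)
N_CONTROL_SITES = 6


def landscape_id_for(cover: float) -> str:
    return f"L{cover:g}"


def control_id_for(cover: float) -> str:
    return f"C{cover:g}"


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic study.

    ``coefficients`` are on the log-link scale and keyed by the
    generating model's parameter names (as produced by
    :func:`fragfit.candidate_models.enumerate_candidates` for the
    landscape ids ``L<cover>``).  ``dispersion_k`` is the
    negative-binomial dispersion of the per-site totals; ``inf`` means
    Poisson.  ``control_mean`` is the expected per-site guild total in
    the continuously forested control areas.
    """

    name: str
    landscapes: tuple[tuple[float, int], ...] = tuple(
        (c, DEFAULT_N_PATCHES) for c in DEFAULT_COVERS
    )
    area_range_ha: tuple[float, float] = DEFAULT_AREA_RANGE
    generating_model: str = "A"
    coefficients: dict[str, float] = field(default_factory=dict)
    dispersion_k: float = math.inf
    guild: str = "specialist"
    n_years: int = 2
    n_species: int = 27
    abundance_profile_ratio: float = 0.75
    n_control_sites: int = N_CONTROL_SITES
    control_mean: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "landscapes",
            tuple((float(c), int(n)) for c, n in self.landscapes),
        )
        object.__setattr__(
            self, "area_range_ha",
            tuple(float(a) for a in self.area_range_ha),
        )
        if self.area_range_ha[0] <= 0 or self.area_range_ha[1] <= self.area_range_ha[0]:
            raise ValueError("area_range_ha must be a positive increasing pair")
        if not (self.dispersion_k > 0):
            raise ValueError("dispersion_k must be positive (inf for Poisson)")
        self.model()  # validates generating_model and coefficients

    @property
    def fragmented_ids(self) -> tuple[str, ...]:
        return tuple(landscape_id_for(c) for c, _ in self.landscapes)

    def model(self) -> CandidateModel:
        """The generating candidate model, with coefficient names checked."""
        catalogue = {
            m.model_id: m
            for m in enumerate_candidates(self.fragmented_ids, "abundance")
        }
        if self.generating_model not in catalogue:
            raise ValueError(f"unknown generating model {self.generating_model!r}")
        model = catalogue[self.generating_model]
        expected = set(model.param_names)
        got = set(self.coefficients)
        if expected != got:
            raise ValueError(
                f"coefficients for model {self.generating_model} must be keyed by "
                f"{sorted(expected)}, got {sorted(got)}"
            )
        return model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscapes"] = [list(pair) for pair in self.landscapes]
        d["area_range_ha"] = list(self.area_range_ha)
        d["dispersion_k"] = (
            "inf" if math.isinf(self.dispersion_k) else float(self.dispersion_k)
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        d["landscapes"] = tuple(tuple(pair) for pair in d["landscapes"])
        d["area_range_ha"] = tuple(d["area_range_ha"])
        k = d.get("dispersion_k", math.inf)
        d["dispersion_k"] = math.inf if k in ("inf", None) else float(k)
        return cls(**d)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=True))


def load_scenario(path: str | Path) -> Scenario:
    return Scenario.from_dict(yaml.safe_load(Path(path).read_text()))


def preset_scenarios() -> dict[str, Scenario]:
    """Named scenarios covering the hypothesised biodiversity regimes.

    Coefficients are illustrative (chosen from the qualitative structure
    of the regimes and typical small-mammal capture totals), not field
    estimates; see docs/methods.md.
    """
    ln = math.log
    presets = {
        "null": Scenario(
            name="null", generating_model="A",
            coefficients={"c_all": ln(5.0)}, control_mean=5.0,
        ),
        "patch_area": Scenario(
            name="patch_area", generating_model="B",
            coefficients={"a_all": 1.0, "b_all": 1.0}, control_mean=15.0,
        ),
        "landscape": Scenario(
            name="landscape", generating_model="C",
            coefficients={"c_L50": ln(30.0), "c_L30": ln(12.0), "c_L10": ln(3.0)},
            control_mean=30.0,
        ),
        "andren_threshold": Scenario(
            name="andren_threshold", generating_model="E",
            coefficients={
                "c_L50": ln(30.0), "a_L30": 1.0, "a_L10": 0.0, "b_shared": 1.0,
            },
            control_mean=35.0,
        ),
        "regime_shift": Scenario(
            name="regime_shift", generating_model="F",
            coefficients={
                "c_L50": ln(30.0), "a_L30": 1.0, "b_L30": 1.0, "c_L10": ln(3.0),
            },
            control_mean=35.0,
        ),
        "generalist_release": Scenario(
            name="generalist_release", generating_model="C", guild="generalist",
            coefficients={"c_L50": ln(5.0), "c_L30": ln(13.0), "c_L10": ln(27.0)},
            dispersion_k=3.0, n_species=12, control_mean=5.0,
        ),
    }
    return presets


def _species_probs(scenario: Scenario) -> np.ndarray:
    w = scenario.abundance_profile_ratio ** np.arange(scenario.n_species)
    return w / w.sum()


def _species_ids(scenario: Scenario) -> list[str]:
    prefix = "spec" if scenario.guild == "specialist" else "gen"
    return [f"{prefix}_sp{i + 1:02d}" for i in range(scenario.n_species)]


def _build_frames(scenario: Scenario, rng: np.random.Generator):
    land_rows, site_rows = [], []
    lo, hi = np.log10(scenario.area_range_ha[0]), np.log10(scenario.area_range_ha[1])
    for cover, n_patches in scenario.landscapes:
        lid, cid = landscape_id_for(cover), control_id_for(cover)
        land_rows.append(
            {"landscape_id": lid, "forest_cover_percent": cover,
             "is_control": False, "paired_with": ""}
        )
        land_rows.append(
            {"landscape_id": cid, "forest_cover_percent": 100.0,
             "is_control": True, "paired_with": lid}
        )
        areas = 10.0 ** rng.uniform(lo, hi, size=n_patches)
        for j, area in enumerate(areas):
            site_rows.append(
                {"site_id": f"{lid}_S{j + 1:02d}", "landscape_id": lid,
                 "patch_area_ha": float(area), "is_control": False}
            )
        for j in range(scenario.n_control_sites):
            site_rows.append(
                {"site_id": f"{cid}_S{j + 1:02d}", "landscape_id": cid,
                 "patch_area_ha": float("nan"), "is_control": True}
            )
    return pd.DataFrame(land_rows), pd.DataFrame(site_rows)


def generate(
    scenario: Scenario,
    landscapes: pd.DataFrame | None = None,
    sites: pd.DataFrame | None = None,
) -> Study:
    """Draw one synthetic study from a scenario.

    A fixed ``scenario.seed`` gives bit-identical output; per-site count
    draws use sub-streams spawned deterministically from that seed, so
    site-level draws are stable under reordering.  Passing ``landscapes``
    and ``sites`` frames (e.g. from a previous call with another guild's
    scenario) reuses that layout instead of drawing new patch areas.
    """
    model = scenario.model()
    root = np.random.SeedSequence(scenario.seed)
    layout_seq, counts_seq = root.spawn(2)
    if (landscapes is None) != (sites is None):
        raise ValueError("pass both landscapes and sites, or neither")
    if landscapes is None:
        landscapes, sites = _build_frames(
            scenario, np.random.default_rng(layout_seq)
        )
    assert sites is not None

    species_ids = _species_ids(scenario)
    probs = _species_probs(scenario)
    k = scenario.dispersion_k
    coef = scenario.coefficients

    cap_rows = []
    site_streams = counts_seq.spawn(len(sites))
    for (_, row), stream in zip(sites.iterrows(), site_streams):
        rng = np.random.default_rng(stream)
        if bool(row["is_control"]):
            mu = scenario.control_mean
        else:
            comp = model.component_for(str(row["landscape_id"]))
            x = float(np.log10(row["patch_area_ha"]))
            mu = mean_function(
                comp.form, [coef[p] for p in comp.param_names], x, offset=1.0
            )
        if math.isinf(k):
            total = int(rng.poisson(mu))
        else:
            total = int(rng.negative_binomial(k, k / (k + mu)))
        if total == 0:
            continue
        per_species = rng.multinomial(total, probs)
        for sp, n_sp in zip(species_ids, per_species):
            if n_sp == 0:
                continue
            year1 = int(rng.binomial(n_sp, 0.5))
            for year, n_year in ((1, year1), (2, int(n_sp) - year1)):
                if n_year > 0:
                    cap_rows.append(
                        {"site_id": row["site_id"], "species_id": sp,
                         "year": year, "individuals": n_year}
                    )

    captures = pd.DataFrame(
        cap_rows, columns=["site_id", "species_id", "year", "individuals"]
    )
    species = pd.DataFrame(
        {"species_id": species_ids, "guild": scenario.guild}
    )
    return Study(
        landscapes=landscapes.copy(), sites=sites.copy(),
        species=species, captures=captures,
    )
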