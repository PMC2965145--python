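"""Domain types, tabular I/O and response construction for patch-survey studies.

A study consists of four delimited text tables (comma-separated, UTF-8,
header row):

``landscapes``
    ``landscape_id, forest_cover_percent, is_control, paired_with`` —
    one row per landscape.  Fragmented landscapes carry a forest-cover
    percentage; a control (continuously forested) landscape is paired to
    exactly one fragmented landscape via ``paired_with``.
``sites``
    ``site_id, landscape_id, patch_area_ha, is_control`` — one row per
    trapping site.  Control sites sit in continuous forest and carry no
    patch area (empty field).
``species``
    ``species_id, guild`` with guild in {specialist, generalist}.
``captures``
    ``site_id, species_id, year, individuals`` — individual counts per
    site, species and sampling year (1 or 2); at most one row per
    combination.

The per-site responses entering the count models are

* **abundance** — total individuals of a guild over both years, and
* **richness response** — the per-year species counts summed over the two
  years (equivalently twice the mean yearly richness), fitted with a
  fixed multiplicative offset of 2 so that model coefficients are on the
  per-year scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "RICHNESS_OFFSET",
    "StudyValidationError",
    "Study",
    "SiteResponse",
    "load_study",
    "write_study",
    "aggregate_responses",
    "sampling_effort",
]

GUILDS = ("specialist", "generalist")

#: Multiplicative offset for the richness response: two sampling years.
RICHNESS_OFFSET = 2


class StudyValidationError(ValueError):
    """Raised when a study table violates the schema or cross-references."""


LANDSCAPE_COLUMNS = ["landscape_id", "forest_cover_percent", "is_control", "paired_with"]
SITE_COLUMNS = ["site_id", "landscape_id", "patch_area_ha", "is_control"]
SPECIES_COLUMNS = ["species_id", "guild"]
CAPTURE_COLUMNS = ["site_id", "species_id", "year", "individuals"]


@dataclass
class Study:
    """Validated container for the four study tables.

    All tables are plain :class:`pandas.DataFrame` objects with the
    documented column schemas; `validate()` is called on construction.
    """

    landscapes: pd.DataFrame
    sites: pd.DataFrame
    species: pd.DataFrame
    captures: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ---------------------------------------------------
    @property
    def fragmented_landscape_ids(self) -> list[str]:
        """Fragmented landscape ids ordered from most to least forested."""
        frag = self.landscapes[~self.landscapes["is_control"]]
        frag = frag.sort_values("forest_cover_percent", ascending=False)
        return list(frag["landscape_id"])

    @property
    def fragmented_sites(self) -> pd.DataFrame:
        return self.sites[~self.sites["is_control"]].copy()

    def control_pair(self, fragmented_id: str) -> str:
        """Id of the control landscape paired with ``fragmented_id``."""
        ctrl = self.landscapes[
            self.landscapes["is_control"]
            & (self.landscapes["paired_with"] == fragmented_id)
        ]
        if len(ctrl) != 1:
            raise StudyValidationError(
                f"landscape {fragmented_id!r} has {len(ctrl)} paired controls, expected 1"
            )
        return str(ctrl["landscape_id"].iloc[0])

    def guild_species(self, guild: str) -> list[str]:
        if guild not in GUILDS:
            raise StudyValidationError(f"unknown guild {guild!r}")
        return list(self.species.loc[self.species["guild"] == guild, "species_id"])

    def log10_area(self) -> pd.Series:
        """log10 patch area (ha) indexed by site_id; NaN for control sites."""
        s = pd.Series(
            np.log10(self.sites["patch_area_ha"].to_numpy(dtype=float)),
            index=self.sites["site_id"],
        )
        return s

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for df, cols, name in (
            (self.landscapes, LANDSCAPE_COLUMNS, "landscapes"),
            (self.sites, SITE_COLUMNS, "sites"),
            (self.species, SPECIES_COLUMNS, "species"),
            (self.captures, CAPTURE_COLUMNS, "captures"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise StudyValidationError(f"{name} table missing columns {missing}")

        land = self.landscapes
        if land["landscape_id"].duplicated().any():
            raise StudyValidationError("duplicate landscape_id in landscapes table")
        frag = land[~land["is_control"]]
        covers = frag["forest_cover_percent"].to_numpy(dtype=float)
        if np.any(~((covers > 0) & (covers <= 100))):
            raise StudyValidationError("forest_cover_percent must lie in (0, 100]")
        if len(np.unique(covers)) != len(covers):
            raise StudyValidationError(
                "fragmented landscapes must have distinct forest cover"
            )
        for _, row in land[land["is_control"]].iterrows():
            target = row["paired_with"]
            if target not in set(frag["landscape_id"]):
                raise StudyValidationError(
                    f"control landscape {row['landscape_id']!r} pairs to unknown "
                    f"fragmented landscape {target!r}"
                )

        sites = self.sites
        if sites["site_id"].duplicated().any():
            raise StudyValidationError("duplicate site_id in sites table")
        unknown = set(sites["landscape_id"]) - set(land["landscape_id"])
        if unknown:
            raise StudyValidationError(f"sites reference unknown landscapes {sorted(unknown)}")
        ctrl_land = set(land.loc[land["is_control"], "landscape_id"])
        for idx, row in sites.iterrows():
            in_ctrl = row["landscape_id"] in ctrl_land
            if bool(row["is_control"]) != in_ctrl:
                raise StudyValidationError(
                    f"site {row['site_id']!r} control flag disagrees with its landscape"
                )
            area = row["patch_area_ha"]
            if in_ctrl:
                if not (area is None or (isinstance(area, float) and math.isnan(area))):
                    raise StudyValidationError(
                        f"control site {row['site_id']!r} must not carry a patch area"
                    )
            else:
                if not (isinstance(area, (int, float)) and float(area) > 0):
                    raise StudyValidationError(
                        f"site {row['site_id']!r} has non-positive patch area {area!r}"
                    )

        sp = self.species
        if sp["species_id"].duplicated().any():
            raise StudyValidationError("duplicate species_id in species table")
        bad = sp[~sp["guild"].isin(GUILDS)]
        if len(bad):
            raise StudyValidationError(
                f"unknown guild {bad['guild'].iloc[0]!r} for species "
                f"{bad['species_id'].iloc[0]!r}"
            )

        cap = self.captures
        known_sites = set(sites["site_id"])
        known_species = set(sp["species_id"])
        for idx, row in cap.iterrows():
            if row["site_id"] not in known_sites:
                raise StudyValidationError(
                    f"captures row {idx}: unknown site {row['site_id']!r}"
                )
            if row["species_id"] not in known_species:
                raise StudyValidationError(
                    f"captures row {idx}: unknown species {row['species_id']!r}"
                )
            year = row["year"]
            if year not in (1, 2):
                raise StudyValidationError(
                    f"captures row {idx}: year must be 1 or 2, got {year!r}"
                )
            n = row["individuals"]
            if not (float(n).is_integer() and float(n) >= 0):
                raise StudyValidationError(
                    f"captures row {idx}: individuals must be a non-negative "
                    f"integer, got {n!r}"
                )
        dup = cap.duplicated(subset=["site_id", "species_id", "year"])
        if dup.any():
            row = cap[dup].iloc[0]
            raise StudyValidationError(
                f"duplicate capture entry for (site={row['site_id']!r}, "
                f"species={row['species_id']!r}, year={row['year']!r})"
            )


@dataclass(frozen=True)
class SiteResponse:
    """Per-site, per-guild responses entering the count models.

    ``abundance`` is the total number of individuals of the guild caught
    at the site over both years.  ``richness_response`` is the sum of the
    two per-year species counts (= 2 x mean yearly richness) and is
    always an integer; it is modelled with the fixed offset
    :data:`RICHNESS_OFFSET`.
    """

    site_id: str
    guild: str
    abundance: int
    richness_response: int
    offset: int = field(default=RICHNESS_OFFSET)


def _read_table(path: str | Path, columns: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StudyValidationError(f"{name} table at {path} missing columns {missing}")
    return df


def load_study(
    site_path: str | Path,
    species_path: str | Path,
    capture_path: str | Path,
    landscape_path: str | Path | None = None,
    landscapes: pd.DataFrame | None = None,
) -> Study:
    """Read and cross-validate the study tables.

    Landscape metadata (forest cover, control pairing) comes either from a
    fourth CSV (``landscape_path``) or from an in-memory frame
    (``landscapes``); exactly one must be given.
    """
    if (landscape_path is None) == (landscapes is None):
        raise StudyValidationError(
            "provide exactly one of landscape_path or landscapes"
        )
    if landscape_path is not None:
        landscapes = _read_table(landscape_path, LANDSCAPE_COLUMNS, "landscapes")
    assert landscapes is not None
    landscapes = landscapes.copy()
    landscapes["is_control"] = landscapes["is_control"].astype(bool)

    sites = _read_table(site_path, SITE_COLUMNS, "sites")
    sites["is_control"] = sites["is_control"].astype(bool)
    species = _read_table(species_path, SPECIES_COLUMNS, "species")
    captures = _read_table(capture_path, CAPTURE_COLUMNS, "captures")
    return Study(landscapes=landscapes, sites=sites, species=species, captures=captures)


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write the four study tables as CSV; returns the paths written.

    The dialect round-trips through :func:`load_study` unchanged.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "landscapes": out / "landscapes.csv",
        "sites": out / "sites.csv",
        "species": out / "species.csv",
        "captures": out / "captures.csv",
    }
    study.landscapes.to_csv(paths["landscapes"], index=False)
    study.sites.to_csv(paths["sites"], index=False)
    study.species.to_csv(paths["species"], index=False)
    study.captures.to_csv(paths["captures"], index=False)
    return paths


def aggregate_responses(study: Study, guild: str) -> list[SiteResponse]:
    """Build one :class:`SiteResponse` per surveyed site for a guild.

    Sites with no captures of the guild appear as explicit zero rows:
    the even-effort design makes every surveyed site a data point, and
    dropping zeros would bias the constant-model likelihoods.
    """
    guild_sp = set(study.guild_species(guild))
    if not guild_sp and guild not in GUILDS:
        raise StudyValidationError(f"guild {guild!r} absent from species table")

    cap = study.captures
    cap = cap[cap["species_id"].isin(guild_sp) & (cap["individuals"] > 0)]
    abundance = cap.groupby("site_id")["individuals"].sum()
    # yearly species counts, then summed over the two years
    yearly = cap.groupby(["site_id", "year"])["species_id"].nunique()
    rich = yearly.groupby("site_id").sum()

    responses = []
    for site_id in study.sites["site_id"]:
        responses.append(
            SiteResponse(
                site_id=str(site_id),
                guild=guild,
                abundance=int(abundance.get(site_id, 0)),
                richness_response=int(rich.get(site_id, 0)),
            )
        )
    return responses


def sampling_effort(
    n_traps_per_site: int, n_sessions: int, nights_per_session: int, n_sites: int
) -> tuple[int, int, int]:
    """Trapping-effort arithmetic for an even-effort pitfall design.

    Returns ``(nights_per_site, trapnights_per_site, trapnights_total)``.
    """
    args = (n_traps_per_site, n_sessions, nights_per_session, n_sites)
    if any((not float(a).is_integer()) or a <= 0 for a in args):
        raise ValueError(f"all effort arguments must be positive integers, got {args}")
    nights_per_site = n_sessions * nights_per_session
    trapnights_per_site = n_traps_per_site * nights_per_site
    return nights_per_site, trapnights_per_site, trapnights_per_site * n_sites
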