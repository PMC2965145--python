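"""Landscape-scale (gamma) diversity statistics.

Sample-based rarefaction (the analytic Mao Tau expectation with an exact
hypergeometric variance), incidence-based richness estimators (Chao2,
first-order jackknife), Bray–Curtis similarity on presence/absence data
(equivalent to the Sørensen index), and representation percentages of
fragmented landscapes against their paired continuously forested
controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .data_model import Study

__all__ = [
    "IncidenceMatrix",
    "incidence_from_study",
    "accumulation_curve",
    "chao2",
    "jackknife1",
    "bray_curtis_presence",
    "representation_percent",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Species x sample presence/absence matrix (one sample = one site)."""

    matrix: np.ndarray  # binary, species rows x sample columns
    species_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValueError("matrix shape must be (n_species, n_samples)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if m.size and np.any(m.sum(axis=1) == 0):
            raise ValueError("retained species rows must occur in >=1 sample")

    @property
    def H(self) -> int:
        """Number of samples."""
        return len(self.sample_ids)

    @property
    def S_obs(self) -> int:
        """Observed species richness."""
        return len(self.species_ids)

    @property
    def incidence_counts(self) -> np.ndarray:
        """H_i: number of samples containing each species."""
        return np.asarray(self.matrix).sum(axis=1).astype(int)

    def q(self, r: int) -> int:
        """Number of species found in exactly r samples."""
        return int(np.sum(self.incidence_counts == r))

    @property
    def presence_set(self) -> frozenset[str]:
        return frozenset(self.species_ids)


def incidence_from_study(study: Study, guild: str, landscape_id: str) -> IncidenceMatrix:
    """Incidence matrix for one guild in one landscape, pooling years."""
    sites = study.sites.loc[
        study.sites["landscape_id"] == landscape_id, "site_id"
    ].astype(str)
    if sites.empty:
        raise ValueError(f"landscape {landscape_id!r} has no sites")
    guild_sp = study.guild_species(guild)
    cap = study.captures
    cap = cap[
        cap["site_id"].isin(set(sites))
        & cap["species_id"].isin(set(guild_sp))
        & (cap["individuals"] > 0)
    ]
    present = cap.groupby(["species_id", "site_id"]).size()
    species = sorted({sp for sp, _ in present.index})
    mat = np.zeros((len(species), len(sites)), dtype=int)
    col = {sid: j for j, sid in enumerate(sites)}
    row = {sp: i for i, sp in enumerate(species)}
    for (sp, sid) in present.index:
        mat[row[sp], col[str(sid)]] = 1
    return IncidenceMatrix(mat, tuple(species), tuple(sites))


def accumulation_curve(inc: IncidenceMatrix, z: float = 1.96) -> pd.DataFrame:
    """Sample-based species-accumulation curve with 95% confidence band.

    For each number of pooled samples h = 1..H the expected richness is
    the Mao Tau rarefaction value

        tau(h) = S_obs - sum_i C(H - H_i, h) / C(H, h),

    the mean richness over all h-sample subsets drawn without
    replacement.  The standard deviation is the exact subsampling value,
    computed from the pairwise joint-absence counts, so sd(H) = 0 and
    the band matches Monte-Carlo subsampling exactly.
    """
    H = inc.H
    if H < 1 or inc.S_obs < 1:
        raise ValueError("accumulation_curve requires a non-empty incidence matrix")
    m = np.asarray(inc.matrix, dtype=int)
    Hi = inc.incidence_counts
    absent = 1 - m
    # samples containing neither species i nor j
    joint_absent = absent @ absent.T

    rows = []
    for h in range(1, H + 1):
        denom = comb(H, h)
        # alpha_i: probability species i is missed by an h-sample subset
        alpha = np.array([comb(H - hi, h) for hi in Hi], dtype=float) / denom
        tau = inc.S_obs - alpha.sum()
        # exact variance of the number of missed species
        pair = np.array(
            [[comb(joint_absent[i, j], h) for j in range(inc.S_obs)]
             for i in range(inc.S_obs)],
            dtype=float,
        ) / denom
        cov = pair - np.outer(alpha, alpha)
        np.fill_diagonal(cov, alpha * (1.0 - alpha))
        var = max(float(cov.sum()), 0.0)
        sd = np.sqrt(var)
        rows.append(
            {"h": h, "tau": tau, "sd": sd, "lo95": tau - z * sd, "hi95": tau + z * sd}
        )
    return pd.DataFrame(rows)


def chao2(inc: IncidenceMatrix) -> float:
    """Chao2 incidence-based richness estimator.

    Classic form S_obs + q1^2/(2 q2); the bias-corrected form
    S_obs + q1(q1-1)/(2(q2+1)) is used when no species occurs in exactly
    two samples.
    """
    s, q1, q2 = inc.S_obs, inc.q(1), inc.q(2)
    if q2 > 0:
        return s + q1 * q1 / (2.0 * q2)
    return s + q1 * (q1 - 1) / 2.0


def jackknife1(inc: IncidenceMatrix) -> float:
    """First-order jackknife richness estimator: S_obs + q1 (H-1)/H."""
    if inc.H < 2:
        raise ValueError("jackknife1 requires at least two samples")
    return inc.S_obs + inc.q(1) * (inc.H - 1) / inc.H


def bray_curtis_presence(x: frozenset | set, y: frozenset | set) -> float:
    """Bray–Curtis similarity on presence/absence, in percent.

    100 * 2a / (2a + b + c) with a shared species, b only in x, c only
    in y; on binary data this equals the Sørensen index.
    """
    x, y = set(x), set(y)
    if not x and not y:
        raise ValueError("Bray-Curtis undefined for two empty species sets")
    a = len(x & y)
    b = len(x - y)
    c = len(y - x)
    return 100.0 * 2 * a / (2 * a + b + c)


def representation_percent(fragment_species: frozenset | set,
                           control_species: frozenset | set) -> float:
    """Percent of the control species pool represented in the fragments."""
    control = set(control_species)
    if not control:
        raise ValueError("control species set must be non-empty")
    return 100.0 * len(set(fragment_species) & control) / len(control)
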