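"""The eight candidate species–patch-area models for a three-landscape design.

Each candidate is a structured hypothesis about how a guild's per-site
abundance or richness varies with log10 patch area across three
fragmented landscapes ordered by remaining forest cover (most forested,
intermediate, most deforested).  Every model is a set of per-landscape
component functions — constant, or linear in log10 area — possibly
sharing coefficients across landscapes:

========  ===========================================================
id        structure
========  ===========================================================
A         one constant shared by all three landscapes (null)
B         one linear function shared by all three (patch-area effect)
C         one constant per landscape (landscape-context effect)
D         per-landscape intercepts, one shared slope (context + area)
D2        per-landscape intercepts and slopes
E         constant in the most forested landscape; linear in the two
          most deforested, per-landscape intercepts, shared slope
          (patch-area effect beyond a fragmentation threshold)
E2        as E, with landscape-specific slopes
F         constants in the most forested and the most deforested
          landscapes, linear in the intermediate one (regime shift:
          a patch-area effect only at intermediate forest loss)
========  ===========================================================

Error-distribution policy: abundance is negative-binomial when the model
has no patch-area effect (all components constant — A and C) and Poisson
otherwise; richness is Poisson in every model.  The negative-binomial
dispersion is a single extra free parameter shared across components and
is included in K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "MODEL_IDS",
    "ComponentFunction",
    "CandidateModel",
    "enumerate_candidates",
    "param_count",
    "catalogue_description",
]

MODEL_IDS = ("A", "B", "C", "D", "D2", "E", "E2", "F")

RESPONSE_KINDS = ("abundance", "richness")


@dataclass(frozen=True)
class ComponentFunction:
    """One component of a candidate model.

    ``param_names`` index into the model's ordered coefficient vector:
    ``("c",)`` for a constant, ``("a", "b")`` (intercept, slope on log10
    area) for a linear component.  Shared coefficients carry the same
    name across components.
    """

    landscape_ids: tuple[str, ...]
    form: str  # "constant" | "linear"
    param_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.form not in ("constant", "linear"):
            raise ValueError(f"unknown component form {self.form!r}")
        expected = 1 if self.form == "constant" else 2
        if len(self.param_names) != expected:
            raise ValueError(
                f"{self.form} component needs {expected} parameter name(s), "
                f"got {self.param_names}"
            )


@dataclass(frozen=True)
class CandidateModel:
    """A candidate model: components + error distribution + bookkeeping."""

    model_id: str
    components: tuple[ComponentFunction, ...]
    distribution: str  # "poisson" | "negbin"
    response_kind: str
    param_names: tuple[str, ...]  # free coefficients, dispersion excluded

    def __post_init__(self) -> None:
        if self.distribution not in ("poisson", "negbin"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        seen: dict[str, str] = {}
        for comp in self.components:
            for lid in comp.landscape_ids:
                if lid in seen:
                    raise ValueError(
                        f"model {self.model_id}: landscape {lid!r} covered twice"
                    )
                seen[lid] = comp.form

    @property
    def K(self) -> int:
        """Number of estimated parameters (dispersion included for negbin)."""
        return len(self.param_names) + (1 if self.distribution == "negbin" else 0)

    def component_for(self, landscape_id: str) -> ComponentFunction:
        for comp in self.components:
            if landscape_id in comp.landscape_ids:
                return comp
        raise KeyError(f"model {self.model_id} covers no landscape {landscape_id!r}")

    def describe(self) -> dict:
        return {
            "model_id": self.model_id,
            "distribution": self.distribution,
            "response_kind": self.response_kind,
            "K": self.K,
            "components": [
                {
                    "landscapes": list(c.landscape_ids),
                    "form": c.form,
                    "params": list(c.param_names),
                }
                for c in self.components
            ],
        }


def _collect_param_names(components: Sequence[ComponentFunction]) -> tuple[str, ...]:
    names: list[str] = []
    for comp in components:
        for name in comp.param_names:
            if name not in names:
                names.append(name)
    return tuple(names)


def _distribution(components: Sequence[ComponentFunction], response_kind: str) -> str:
    if response_kind == "richness":
        return "poisson"
    all_constant = all(c.form == "constant" for c in components)
    return "negbin" if all_constant else "poisson"


def enumerate_candidates(
    landscapes_ordered_by_cover: Sequence[str], response_kind: str
) -> list[CandidateModel]:
    """Build the eight-candidate set for three fragmented landscapes.

    ``landscapes_ordered_by_cover`` lists the fragmented landscape ids
    from most to least forested; ``response_kind`` is ``"abundance"`` or
    ``"richness"`` and fixes the error-distribution policy.
    """
    if response_kind not in RESPONSE_KINDS:
        raise ValueError(f"response_kind must be one of {RESPONSE_KINDS}")
    lids = tuple(str(x) for x in landscapes_ordered_by_cover)
    if len(lids) != 3 or len(set(lids)) != 3:
        raise ValueError(
            "the candidate-model catalogue is defined for exactly three "
            f"distinct fragmented landscapes, got {lids}"
        )
    hi, mid, lo = lids  # most forested, intermediate, most deforested

    def constant(*ls: str, tag: str) -> ComponentFunction:
        return ComponentFunction(tuple(ls), "constant", (f"c_{tag}",))

    def linear(*ls: str, tag: str, slope: str) -> ComponentFunction:
        return ComponentFunction(tuple(ls), "linear", (f"a_{tag}", slope))

    structures: dict[str, tuple[ComponentFunction, ...]] = {
        "A": (constant(hi, mid, lo, tag="all"),),
        "B": (linear(hi, mid, lo, tag="all", slope="b_all"),),
        "C": (constant(hi, tag=hi), constant(mid, tag=mid), constant(lo, tag=lo)),
        "D": (
            linear(hi, tag=hi, slope="b_shared"),
            linear(mid, tag=mid, slope="b_shared"),
            linear(lo, tag=lo, slope="b_shared"),
        ),
        "D2": (
            linear(hi, tag=hi, slope=f"b_{hi}"),
            linear(mid, tag=mid, slope=f"b_{mid}"),
            linear(lo, tag=lo, slope=f"b_{lo}"),
        ),
        "E": (
            constant(hi, tag=hi),
            linear(mid, tag=mid, slope="b_shared"),
            linear(lo, tag=lo, slope="b_shared"),
        ),
        "E2": (
            constant(hi, tag=hi),
            linear(mid, tag=mid, slope=f"b_{mid}"),
            linear(lo, tag=lo, slope=f"b_{lo}"),
        ),
        "F": (
            constant(hi, tag=hi),
            linear(mid, tag=mid, slope=f"b_{mid}"),
            constant(lo, tag=lo),
        ),
    }

    models = []
    for mid_id in MODEL_IDS:
        comps = structures[mid_id]
        models.append(
            CandidateModel(
                model_id=mid_id,
                components=comps,
                distribution=_distribution(comps, response_kind),
                response_kind=response_kind,
                param_names=_collect_param_names(comps),
            )
        )
    return models


def param_count(model: CandidateModel, response_kind: str | None = None) -> int:
    """K for a candidate model (free coefficients + NB dispersion if any)."""
    if response_kind is not None and response_kind != model.response_kind:
        raise ValueError(
            f"model {model.model_id} was built for {model.response_kind!r}, "
            f"not {response_kind!r}"
        )
    return model.K


def catalogue_description(models: Sequence[CandidateModel]) -> str:
    """Human-readable JSON description of a candidate set (for reports)."""
    return json.dumps([m.describe() for m in models], indent=2)
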