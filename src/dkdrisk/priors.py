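"""Machine-readable registry of literature effect sizes and prevalences.

Each entry describes one literature-informed variable: how prevalent it
is in the source population, its per-level log hazard ratio(s) on the
kidney outcome, and (optionally) weak conditioning associations with
observed covariates used during chained imputation.

Prior scaling for sensitivity analysis acts on the log-HR scale:
``scale=0.5`` shrinks every effect halfway toward the null (HR 1),
``scale=1.5`` amplifies it, and ``scale=0`` produces flat
non-informative priors (all HRs 1, no conditioning).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

from ._errors import DomainError, SchemaError

__all__ = ["PriorSpec", "PriorRegistry", "load_registry", "scale_registry", "default_registry_path"]

_KINDS = {"binary", "ordinal", "quintile", "continuous"}


@dataclass(frozen=True)
class ConditioningTerm:
    """A weak association with an observed covariate, per standardised unit."""

    coef: float
    center: float
    scale: float


@dataclass(frozen=True)
class PriorSpec:
    """Literature prior for one imputed variable."""

    name: str
    kind: str
    prevalence: tuple[float, ...]  # category probabilities; length 1 for binary
    log_hr: tuple[float, ...]      # per non-reference level
    se: tuple[float, ...]
    source: str = ""
    prevalence_se: float = 0.01
    conditioning: dict[str, ConditioningTerm] = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return len(self.prevalence) if self.kind != "binary" else 2

    def hazard_ratios(self) -> tuple[float, ...]:
        return tuple(math.exp(b) for b in self.log_hr)


@dataclass(frozen=True)
class PriorRegistry:
    """All priors plus the current sensitivity scale factor."""

    entries: dict[str, PriorSpec]
    scale: float = 1.0

    def __getitem__(self, name: str) -> PriorSpec:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)


def _as_tuple(x) -> tuple[float, ...]:
    if isinstance(x, (int, float)):
        return (float(x),)
    return tuple(float(v) for v in x)


def _parse_entry(name: str, raw: dict) -> PriorSpec:
    if "kind" not in raw:
        raise SchemaError(f"prior {name!r}: missing field 'kind'")
    kind = raw["kind"]
    if kind not in _KINDS:
        raise SchemaError(f"prior {name!r}: unknown kind {kind!r}")
    if "prevalence" not in raw:
        raise SchemaError(f"prior {name!r}: missing field 'prevalence'")
    prevalence = _as_tuple(raw["prevalence"])
    if kind == "binary":
        if len(prevalence) != 1 or not 0.0 <= prevalence[0] <= 1.0:
            raise SchemaError(f"prior {name!r}: binary prevalence must be one probability")
    else:
        if abs(sum(prevalence) - 1.0) > 1e-9:
            raise SchemaError(
                f"prior {name!r}: field 'prevalence' must sum to 1, got {sum(prevalence)}"
            )
    if "hr" in raw:
        log_hr = tuple(math.log(float(h)) for h in _as_tuple(raw["hr"]))
    elif "log_hr" in raw:
        log_hr = _as_tuple(raw["log_hr"])
    else:
        raise SchemaError(f"prior {name!r}: missing field 'hr' or 'log_hr'")
    if not all(math.isfinite(b) for b in log_hr):
        raise SchemaError(f"prior {name!r}: field 'log_hr' must be finite")
    if "se" in raw:
        se = _as_tuple(raw["se"])
    elif "ci" in raw:
        lo, hi = (float(v) for v in raw["ci"])
        se = (abs(math.log(hi) - math.log(lo)) / 3.92,) * len(log_hr)
    else:
        se = (0.10,) * len(log_hr)
    if len(se) != len(log_hr):
        raise SchemaError(f"prior {name!r}: field 'se' length mismatch with effects")
    if any(s < 0 for s in se):
        raise SchemaError(f"prior {name!r}: field 'se' must be non-negative")
    cond = {}
    for cov, term in raw.get("conditioning", {}).items():
        try:
            cond[cov] = ConditioningTerm(
                coef=float(term["coef"]), center=float(term["center"]), scale=float(term["scale"])
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"prior {name!r}: malformed conditioning for {cov!r}: {exc}")
    return PriorSpec(
        name=name,
        kind=kind,
        prevalence=prevalence,
        log_hr=log_hr,
        se=se,
        source=str(raw.get("source", "")),
        prevalence_se=float(raw.get("prevalence_se", 0.01)),
        conditioning=cond,
    )


def default_registry_path():
    """Path-like handle to the priors shipped with the package."""
    return resources.files("dkdrisk.data") / "priors.json"


def load_registry(path=None) -> PriorRegistry:
    """Load a prior registry from JSON (the shipped default if ``path`` is None)."""
    if path is None:
        raw = json.loads(default_registry_path().read_text())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    if not isinstance(raw, dict) or "entries" not in raw or not raw["entries"]:
        raise SchemaError("prior registry JSON must contain a non-empty 'entries' object")
    entries = {name: _parse_entry(name, spec) for name, spec in raw["entries"].items()}
    registry = PriorRegistry(entries=entries, scale=1.0)
    scale = float(raw.get("scale", 1.0))
    return registry if scale == 1.0 else scale_registry(registry, scale)


def scale_registry(registry: PriorRegistry, factor: float) -> PriorRegistry:
    """Rescale all effects on the log-HR scale; prevalences are untouched.

    ``factor=0`` yields flat priors: every log-HR becomes 0 and
    conditioning associations vanish.  Scaling is multiplicative:
    scaling by ``a`` then ``b`` equals scaling by ``a*b``.
    """
    if not math.isfinite(factor) or factor < 0:
        raise DomainError(f"prior scale factor must be >= 0, got {factor}")
    entries = {}
    for name, spec in registry.entries.items():
        entries[name] = replace(
            spec,
            log_hr=tuple(factor * b for b in spec.log_hr),
            conditioning={
                cov: ConditioningTerm(factor * t.coef, t.center, t.scale)
                for cov, t in spec.conditioning.items()
            },
        )
    return PriorRegistry(entries=entries, scale=registry.scale * factor)
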