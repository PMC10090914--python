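"""Config-driven design runs and report rendering.

A design is described by a small mapping (from CLI flags or a JSON/YAML
config file), dispatched to the appropriate sizing module, and returned
as a :class:`DesignReport` that renders identically to text and JSON —
every number in the text report appears verbatim in the JSON one.

Sample-size calculation is one component of a trial protocol; the
report confines itself to sizes, achieved intervals and the inputs that
produced them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

from . import __version__
from .design_comparative import (
    ComparativeSpec,
    SampleSizeResult,
    inflate_for_dropout,
    noninferiority_n,
    superiority_n,
)
from .design_noncomparative import NoncomparativeDesign, size_noncomparative
from .errors import InvalidInputError

__all__ = ["DesignConfig", "DesignReport", "run_from_config", "render_report"]

DESIGN_KINDS = ("noncomparative", "diag-sup", "diag-noninf", "rct-sup", "rct-noninf")


@dataclass(frozen=True)
class DesignConfig:
    """Validated design request.

    ``percent_convention`` says whether proportion-like parameters
    (p_control, p_new, alpha, power, margin, prevalence) arrive in
    percent (CLI idiom) or as proportions (config-file idiom); they are
    normalized to proportions on construction.  Metric floors for the
    non-comparative design are always in percent.
    """

    design_kind: str
    parameters: dict[str, Any]
    percent_convention: bool = False
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.design_kind not in DESIGN_KINDS:
            raise InvalidInputError(
                f"design_kind must be one of {DESIGN_KINDS}; got "
                f"{self.design_kind!r}")
        object.__setattr__(self, "parameters",
                           self._normalized(dict(self.parameters)))

    _PERCENTABLE = ("p_control", "p_new", "alpha", "power", "margin",
                    "prevalence", "level")

    def _normalized(self, params: dict[str, Any]) -> dict[str, Any]:
        if self.percent_convention:
            for key in self._PERCENTABLE:
                if params.get(key) is not None:
                    params[key] = float(params[key]) / 100.0
        for key in ("prevalence", "level", "alpha", "power"):
            v = params.get(key)
            if v is not None and not 0.0 < float(v) < 1.0:
                raise InvalidInputError(
                    f"{key} must lie strictly in (0, 1); got {v}")
        return params


@dataclass(frozen=True)
class DesignReport:
    """Everything a protocol writer needs from one sizing run."""

    design_kind: str
    inputs: dict[str, Any]
    results: dict[str, Any]
    warnings: tuple[str, ...] = ()
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "design_kind": self.design_kind,
            "inputs": self.inputs,
            "results": self.results,
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DesignReport":
        return cls(design_kind=d["design_kind"], inputs=d["inputs"],
                   results=d["results"], warnings=tuple(d["warnings"]),
                   provenance=d["provenance"])


def _comparative_results(res: SampleSizeResult) -> dict[str, Any]:
    out = {
        "n_per_group": res.n_per_group,
        "n_total": res.n_total,
        "z_alpha": res.z_alpha,
        "z_power": res.z_power,
        "variance_term": res.variance_term,
        "n_unrounded": res.n_unrounded,
    }
    if res.n_inflated is not None:
        out["n_inflated"] = res.n_inflated
        out["inflation_pct"] = res.inflation_pct
    return out


def _noncomparative_results(d: NoncomparativeDesign) -> dict[str, Any]:
    def ci(iv):
        return None if iv is None else {"lower": iv.lower, "upper": iv.upper,
                                        "level": iv.level}
    return {
        "n_primary": d.n_primary,
        "n_alternative": d.n_alternative,
        "n_total": d.n_total,
        "n_cases": d.n_cases,
        "n_controls": d.n_controls,
        "achieved_ci_primary": ci(d.achieved_primary),
        "achieved_ci_alternative": ci(d.achieved_alternative),
    }


def run_from_config(config: DesignConfig) -> DesignReport:
    """Dispatch a validated config to its sizing routine.

    Comparative kinds accept ``p_control``, ``p_new``, ``alpha``,
    ``power``, ``margin`` (non-inferiority only), ``orientation`` and
    ``inflate_pct``; the non-comparative kind accepts
    ``target_lower_primary``/``target_lower_alternative`` (percent),
    ``level``, ``prevalence``, ``override_n`` and ``inflate_pct``.
    """
    p = config.parameters
    warnings: list[str] = []
    kind = config.design_kind

    if kind == "noncomparative":
        design = size_noncomparative(
            target_lower_primary=float(p["target_lower_primary"]),
            target_lower_alternative=float(p["target_lower_alternative"]),
            level=float(p.get("level", 0.95)),
            prevalence=float(p["prevalence"]),
            override_n=tuple(p["override_n"]) if p.get("override_n") else None,
        )
        results = _noncomparative_results(design)
        warnings.extend(design.warnings)
        if p.get("inflate_pct"):
            import math
            pct = float(p["inflate_pct"])
            if not 0.0 <= pct <= 50.0:
                raise InvalidInputError("inflation percentage must lie in [0, 50]")
            results["n_inflated"] = math.ceil(design.n_total * (1 + pct / 100.0))
            results["inflation_pct"] = pct
    else:
        hypothesis = "superiority" if kind.endswith("-sup") else "noninferiority"
        framing = "paired-diagnostic" if kind.startswith("diag-") else "two-arm-rct"
        try:
            spec = ComparativeSpec(
                p_control=float(p["p_control"]),
                p_new=float(p["p_new"]),
                alpha=float(p.get("alpha", 0.05)),
                power=float(p.get("power", 0.90)),
                hypothesis=hypothesis,
                margin=float(p["margin"]) if hypothesis == "noninferiority" else None,
                framing=framing,
                orientation=p.get("orientation", "success"),
            )
        except KeyError as exc:
            raise InvalidInputError(f"missing required parameter: {exc}") from exc
        res = (superiority_n if hypothesis == "superiority"
               else noninferiority_n)(spec)
        if p.get("inflate_pct"):
            res = inflate_for_dropout(res, float(p["inflate_pct"]))
        results = _comparative_results(res)

    return DesignReport(
        design_kind=kind,
        inputs={k: v for k, v in p.items() if v is not None},
        results=results,
        warnings=tuple(warnings),
        provenance={"tool": "dxsize", "version": __version__},
    )


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def render_report(report: DesignReport, format: str = "text") -> str:
    """Serialize a report.  JSON round-trips losslessly; the text
    rendering shows every numeric field the JSON carries."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format != "text":
        raise InvalidInputError(f"unknown report format {format!r}")
    lines = [f"dxsize design report — {report.design_kind}", ""]
    lines.append("Inputs:")
    for k, v in sorted(report.inputs.items()):
        lines.append(f"  {k}: {_fmt(v)}")
    lines.append("Results:")
    for k, v in sorted(report.results.items()):
        if isinstance(v, dict):
            lines.append(f"  {k}:")
            for kk, vv in sorted(v.items()):
                lines.append(f"    {kk}: {_fmt(vv)}")
        else:
            lines.append(f"  {k}: {_fmt(v)}")
    if report.warnings:
        lines.append("Warnings:")
        for w in report.warnings:
            lines.append(f"  - {w}")
    lines.append(f"(dxsize {report.provenance.get('version', '?')}; "
                 "sample-size calculation is one component of a trial "
                 "protocol, not a complete design)")
    return "\n".join(lines)
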