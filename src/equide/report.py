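"""Assemble the full evaluation into one reproducible report bundle.

:func:`run_paper_analysis` runs every stage of the analysis over the
packaged reference dataset with the two packaged equations and returns a
:class:`ReportBundle` that can be serialized to JSON (deterministically)
or rendered as Markdown. All numbers in the bundle are produced by the
library operations; the report layer only rounds for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import __version__
from .dataset import Dataset, load_table1
from .energy import (
    DEFAULT_GE,
    PredictionEquation,
    STANDARD_EQUATIONS,
    de_per_g_digestible_om,
    energy_digestibility,
    gross_energy,
    om_digestibility,
    predict_dataset,
)
from .evaluation import (
    EvaluationResult,
    evaluate_equation,
    pearson,
    residual_nutrient_correlations,
    sd_band_summary,
)

__all__ = ["ReportBundle", "run_paper_analysis", "build_report"]


@dataclass(frozen=True)
class ReportBundle:
    """Everything the evaluation produces, with provenance."""

    provenance: dict
    descriptives: dict
    correlations: dict
    evaluations: dict[str, EvaluationResult]
    sd_bands: dict[str, dict]
    residual_correlations: dict[str, list]

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "descriptives": self.descriptives,
            "correlations": self.correlations,
            "evaluations": {k: v.to_dict() for k, v in self.evaluations.items()},
            "sd_bands": self.sd_bands,
            "residual_correlations": self.residual_correlations,
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        d = self.descriptives
        lines = [
            f"# Digestible-energy equation evaluation — {self.provenance['dataset']}",
            "",
            f"Feeds: {d['n']} ({d['n_mixed_diets']} mixed diets, "
            f"{d['n_mixed_feeds']} mixed feeds); "
            f"{d['n_with_digestible']} with digestible nutrient fractions.",
            "",
            "## Observed digestible energy (kcal/kg DM)",
            "",
            f"min {d['de_obs']['min']:.0f}, max {d['de_obs']['max']:.0f}, "
            f"mean {d['de_obs']['mean']:.0f} ± {d['de_obs']['sd']:.0f} (n−1 SD)",
            "",
            f"DE per g digestible organic matter: "
            f"{d['de_per_g_dom']['mean']:.2f} ± {d['de_per_g_dom']['sd']:.2f} kcal/g "
            f"(n = {d['de_per_g_dom']['n']})",
            "",
            "## Evaluation statistics",
            "",
            "| equation | n | R² | RMSEP | RMSEP % mean | CCC | mean bias (p) | linear bias (p) | ECT % | ER % | ED % |",
            "|---|---|---|---|---|---|---|---|---|---|---|",
        ]
        for name, ev in self.evaluations.items():
            b, dec = ev.bias, ev.decomposition
            lines.append(
                f"| {name} | {ev.n} | {ev.r2:.2f} | {ev.rmsep:.0f} | "
                f"{ev.rmsep_pct_of_mean:.1f} | {ev.ccc:.2f} | "
                f"{b.intercept:.0f} ({b.p_intercept:.2f}) | "
                f"{b.slope:.2f} ({b.p_slope:.4f}) | "
                f"{dec.pct_ect:.2f} | {dec.pct_er:.2f} | {dec.pct_ed:.2f} |"
            )
        lines += ["", "## Correlations with observed DE (n = %d)" % d["n"], ""]
        lines.append("| nutrient | r | p |")
        lines.append("|---|---|---|")
        for name, (r, p) in self.correlations["de_obs_vs_nutrient"].items():
            lines.append(f"| {name} | {r:.2f} | {p:.2g} |")
        lines += ["", "## Residual and fiber correlations", ""]
        lines.append("| equation | x | y | n | r | p |")
        lines.append("|---|---|---|---|---|---|")
        for eq_name, table in self.residual_correlations.items():
            for row in table:
                lines.append(
                    f"| {eq_name} | {row['x']} | {row['y']} | {row['n']} | "
                    f"{row['r']:.2f} | {row['p']:.2g} |"
                )
        lines += ["", "## Observed-DE bands (mean ± 1 sample SD)", ""]
        lines.append("| equation | band | count | signed %err (mean ± SD) | abs %err (mean ± SD) |")
        lines.append("|---|---|---|---|---|")
        for eq_name, band in self.sd_bands.items():
            for label in ("below", "within", "above"):
                info = band["bands"][label]
                if info["count"] == 0:
                    lines.append(f"| {eq_name} | {label} | 0 | — | — |")
                    continue
                sd_s = f"{info['sd_pct_error']:.1f}" if info["sd_pct_error"] is not None else "—"
                sd_a = f"{info['sd_abs_pct_error']:.1f}" if info["sd_abs_pct_error"] is not None else "—"
                lines.append(
                    f"| {eq_name} | {label} | {info['count']} | "
                    f"{info['mean_pct_error']:.1f} ± {sd_s} | "
                    f"{info['mean_abs_pct_error']:.1f} ± {sd_a} |"
                )
        lines.append("")
        return "\n".join(lines)


def build_report(
    ds: Dataset, equations: dict[str, PredictionEquation] | None = None
) -> ReportBundle:
    """Run the full analysis over any dataset with any set of equations."""
    equations = equations or dict(STANDARD_EQUATIONS)
    obs = np.array([r.de_observed for r in ds])
    complete = ds.complete() if any(r.has_digestible for r in ds) else None

    descriptives = {
        "n": len(ds),
        "n_mixed_diets": sum(r.kind == "mixed diet" for r in ds),
        "n_mixed_feeds": sum(r.kind == "mixed feed" for r in ds),
        "n_with_digestible": sum(r.has_digestible for r in ds),
        "composition_ranges": {
            name: [
                float(min(getattr(r.composition, name) for r in ds)),
                float(max(getattr(r.composition, name) for r in ds)),
            ]
            for name in ("cp", "cf", "nfe", "ee")
        },
        "de_obs": {
            "min": float(obs.min()),
            "max": float(obs.max()),
            "mean": float(obs.mean()),
            "sd": float(obs.std(ddof=1)),
        },
    }
    if complete is not None and len(complete) >= 2:
        ratios = np.array([de_per_g_digestible_om(r) for r in complete])
        descriptives["de_per_g_dom"] = {
            "mean": float(ratios.mean()),
            "sd": float(ratios.std(ddof=1)),
            "n": len(complete),
        }

    correlations: dict = {
        "de_obs_vs_nutrient": {
            name: list(pearson(obs, [getattr(r.composition, name) for r in ds]))
            for name in ("cp", "cf", "nfe", "ee")
        }
    }
    if complete is not None and len(complete) >= 3:
        omd = np.array(
            [om_digestibility(r.composition, r.digestible) for r in complete]
        )
        ge = np.array([gross_energy(r.composition, DEFAULT_GE) for r in complete])
        ed_vs_omd = {}
        for name, eq in equations.items():
            pred = predict_dataset(complete, eq)
            edig = np.array(
                [energy_digestibility(p, g) for p, g in zip(pred, ge)]
            )
            ed_vs_omd[name] = list(pearson(edig, omd))
        correlations["energy_dig_vs_om_dig"] = ed_vs_omd

    evaluations = {name: evaluate_equation(ds, eq) for name, eq in equations.items()}
    sd_bands = {
        name: sd_band_summary(ds, predict_dataset(ds, eq)).to_dict()
        for name, eq in equations.items()
    }
    residual_corrs = {
        name: residual_nutrient_correlations(ds, eq)
        for name, eq in equations.items()
        if complete is not None and len(complete) >= 3
    }

    provenance = {
        "package": "equide",
        "version": __version__,
        "dataset": ds.name,
        "equations": {name: eq.to_dict() for name, eq in equations.items()},
        "gross_energy_coefficients": {
            "protein": DEFAULT_GE.protein,
            "fat": DEFAULT_GE.fat,
            "fiber": DEFAULT_GE.fiber,
            "nfe": DEFAULT_GE.nfe,
        },
    }
    return ReportBundle(
        provenance=provenance,
        descriptives=descriptives,
        correlations=correlations,
        evaluations=evaluations,
        sd_bands=sd_bands,
        residual_correlations=residual_corrs,
    )


def run_paper_analysis() -> ReportBundle:
    """Full evaluation of both packaged equations on the packaged dataset."""
    return build_report(load_table1())
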