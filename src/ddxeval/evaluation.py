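"""Model/Results interface tying the evaluation pipeline together.

:class:`DiagnosticAccuracyEvaluation` is built from an assessments table
and a case table (from CSV files, in-memory records, or a simulation
config); :meth:`~DiagnosticAccuracyEvaluation.fit` runs the whole
pipeline — validation, penalty calibration, per-group and per-specialty
metrics, safety cross-tabs, and the group comparison of precision
scores — and returns a :class:`DiagnosticAccuracyResults` carrying the
estimates, their confidence bounds, the inference, and a ``summary()``
table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as m
from .data import (
    Assessment,
    CaseRecord,
    Group,
    Specialty,
    by_group,
    by_specialty,
    finals_from_cases,
    validate_cohort,
    ValidationReport,
)
from .inference import PairwiseComparison, games_howell, levene_test, oneway_anova
from .labels import SynonymMap

__all__ = ["DiagnosticAccuracyEvaluation", "DiagnosticAccuracyResults"]


class DiagnosticAccuracyEvaluation:
    """Evaluation of differential-diagnosis lists against adjudicated
    final diagnoses.

    Parameters
    ----------
    assessments
        One :class:`~ddxeval.data.Assessment` per (case, rater).
    cases
        One :class:`~ddxeval.data.CaseRecord` per case.
    penalty
        ``None`` calibrates the per-incorrect-diagnosis penalty from the
        longest observed differential; a float fixes it.
    conf
        Confidence level for interval estimates.
    """

    def __init__(
        self,
        assessments: Sequence[Assessment],
        cases: Sequence[CaseRecord],
        penalty: float | None = None,
        conf: float = 0.95,
    ):
        if not 0.0 < conf < 1.0:
            raise ValueError("conf must be in (0, 1)")
        self.assessments = list(assessments)
        self.cases = list(cases)
        self.conf = conf
        self.finals = finals_from_cases(self.cases)
        if penalty is None:
            self.scheme = m.calibrate_penalty(self.assessments)
        else:
            max_len = max((len(a.differential) for a in self.assessments), default=1)
            self.scheme = m.PenaltyScheme.fixed(penalty, max_list_len=max(max_len, 1))

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        assessments_path,
        cases_path,
        synonyms_path=None,
        penalty: float | None = None,
        conf: float = 0.95,
        max_list: int = 5,
    ) -> "DiagnosticAccuracyEvaluation":
        from .io import read_assessments, read_cases, read_synonyms

        smap = read_synonyms(synonyms_path) if synonyms_path else SynonymMap.default()
        return cls(
            read_assessments(assessments_path, smap, max_list=max_list),
            read_cases(cases_path, smap),
            penalty=penalty,
            conf=conf,
        )

    @classmethod
    def from_simulation(
        cls, config, penalty: float | None = None, conf: float = 0.95
    ) -> "DiagnosticAccuracyEvaluation":
        from .simulate import simulate_cohort

        cases, assessments = simulate_cohort(config)
        return cls(assessments, cases, penalty=penalty, conf=conf)

    # -- fitting ----------------------------------------------------------

    def _groups_present(self) -> list[Group]:
        present = {a.rater.group for a in self.assessments}
        return [g for g in Group if g in present]

    def _specialties_present(self) -> list[Specialty]:
        present = {a.rater.specialty for a in self.assessments}
        return [s for s in Specialty if s in present and s is not Specialty.NONE]

    def fit(self, agg: str = "case-mean") -> "DiagnosticAccuracyResults":
        """Run the full evaluation.

        ``agg`` controls the observations entering the group comparison
        of precision scores: ``"case-mean"`` uses one value per
        followed-up case per group (the mean across the group's raters);
        ``"rater"`` pools the per-assessment scores.
        """
        if agg not in ("case-mean", "rater"):
            raise ValueError("agg must be 'case-mean' or 'rater'")
        validation = validate_cohort(self.assessments, self.cases)

        rows: list[dict] = []
        safety_rows: list[dict] = []
        selectors = [(g.value, by_group(g)) for g in self._groups_present()]
        selectors += [(s.value, by_specialty(s)) for s in self._specialties_present()]

        safety_tabs: dict[str, dict[str, m.SafetyCrossTab]] = {}
        for label, sel in selectors:
            y = m.diagnostic_yield(self.assessments, sel, conf=self.conf, group=label)
            inc = m.inclusion_rate(self.assessments, self.finals, sel, conf=self.conf, group=label)
            dps = m.group_dps(self.assessments, self.finals, self.scheme, sel, group=label)
            multi = m.multi_diagnosis_rate(self.assessments, sel, group=label)
            for name, res in (
                ("yield", y),
                ("inclusion_rate", inc),
                ("dps", dps),
                ("multi_diagnosis_rate", multi),
            ):
                rows.append(
                    {
                        "group": label,
                        "metric": name,
                        "numerator": res.numerator,
                        "denominator": res.denominator,
                        "estimate_pct": res.estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )

        for g in self._groups_present():
            label = g.value
            mode = m.SafetyMode.FIRST_LISTED if g is Group.AI else m.SafetyMode.SINGLE_ONLY
            fwd = m.safety_forward(self.assessments, self.finals, by_group(g), mode, group=label)
            tabs = {"forward": fwd}
            try:
                tabs["backward"] = m.safety_backward(
                    self.assessments, self.finals, by_group(g), group=label
                )
            except ValueError:
                pass  # no final-cardiac cases in this cohort
            safety_tabs[label] = tabs
            for direction, tab in tabs.items():
                for category, count in sorted(tab.counts.items()):
                    safety_rows.append(
                        {
                            "group": label,
                            "direction": direction,
                            "category": category,
                            "count": count,
                            "total": tab.total,
                        }
                    )

        # group comparison of precision scores
        dps_samples: dict[str, list[float]] = {}
        for g in self._groups_present():
            sel = by_group(g)
            if agg == "case-mean":
                per_case = m.dps_by_case(self.assessments, self.finals, self.scheme, sel)
                dps_samples[g.value] = [per_case[c] for c in sorted(per_case)]
            else:
                dps_samples[g.value] = [
                    m.score_assessment(a, self.finals[a.case_id], self.scheme)
                    for a in self.assessments
                    if sel(a.rater) and a.case_id in self.finals
                ]
        anova = levene = None
        pairwise: list[PairwiseComparison] = []
        if len(dps_samples) >= 2 and all(len(v) >= 2 for v in dps_samples.values()):
            levene = levene_test(list(dps_samples.values()))
            anova = oneway_anova(list(dps_samples.values()))
            pairwise = games_howell(dps_samples, conf=self.conf)

        return DiagnosticAccuracyResults(
            model=self,
            validation=validation,
            metrics=pd.DataFrame(rows),
            safety=pd.DataFrame(safety_rows),
            safety_tabs=safety_tabs,
            dps_samples=dps_samples,
            levene=levene,
            anova=anova,
            pairwise=pairwise,
            agg=agg,
        )


@dataclass
class DiagnosticAccuracyResults:
    """Fitted evaluation: estimates, uncertainty, and diagnostics."""

    model: DiagnosticAccuracyEvaluation
    validation: ValidationReport
    metrics: pd.DataFrame
    safety: pd.DataFrame
    safety_tabs: Mapping[str, Mapping[str, m.SafetyCrossTab]]
    dps_samples: Mapping[str, Sequence[float]]
    levene: tuple[float, float] | None
    anova: tuple[float, float] | None
    pairwise: list[PairwiseComparison]
    agg: str = "case-mean"

    # -- accessors --------------------------------------------------------

    def metric(self, group: str, name: str) -> m.MetricResult:
        row = self.metrics[(self.metrics["group"] == group) & (self.metrics["metric"] == name)]
        if row.empty:
            raise KeyError(f"no metric {name!r} for group {group!r}")
        r = row.iloc[0]
        return m.MetricResult(
            estimate=float(r["estimate_pct"]),
            numerator=float(r["numerator"]),
            denominator=int(r["denominator"]),
            ci_low=None if pd.isna(r["ci_low"]) else float(r["ci_low"]),
            ci_high=None if pd.isna(r["ci_high"]) else float(r["ci_high"]),
            group=group,
        )

    @property
    def penalty(self) -> float:
        return self.model.scheme.penalty

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "mean_diff": c.mean_diff,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_value": c.p_value,
                    "df": c.df,
                    "flagged": c.flagged,
                }
                for c in self.pairwise
            ]
        )

    def inference_dict(self) -> dict:
        out: dict = {"dps_aggregation": self.agg}
        if self.levene is not None:
            out["levene"] = {"statistic": self.levene[0], "p": self.levene[1]}
        if self.anova is not None:
            out["anova"] = {"F": self.anova[0], "p": self.anova[1]}
        out["games_howell"] = self.pairwise_frame().to_dict(orient="records")
        return out

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table (percentages to one decimal)."""
        lines = [
            "Differential-diagnosis evaluation",
            "=" * 64,
            self.validation.summary(),
            f"penalty per incorrect diagnosis: {self.model.scheme.penalty:g} "
            f"({self.model.scheme.source.value.lower()}, "
            f"max list length {self.model.scheme.max_list_len})",
            "",
            f"{'group':<22}{'yield':>12}{'inclusion':>12}{'DPS':>9}",
            "-" * 55,
        ]
        for group in self.metrics["group"].unique():
            y = self.metric(group, "yield")
            inc = self.metric(group, "inclusion_rate")
            dps = self.metric(group, "dps")
            lines.append(
                f"{group:<22}{y.estimate:>11.1f}%{inc.estimate:>11.1f}%{dps.estimate:>8.1f}%"
            )
        if self.anova is not None:
            lines += [
                "",
                f"Levene W = {self.levene[0]:.3f} (p = {self.levene[1]:.4f}); "
                f"ANOVA F = {self.anova[0]:.3f} (p = {self.anova[1]:.4f}) "
                f"[{self.agg} DPS]",
            ]
            for c in self.pairwise:
                flag = "  (flagged)" if c.flagged else ""
                lines.append(
                    f"  {c.group_a} vs {c.group_b}: diff {c.mean_diff:+.3f} "
                    f"[{c.ci_low:.3f}, {c.ci_high:.3f}], p = {c.p_value:.4f}{flag}"
                )
        return "\n".join(lines)

    def to_csv(self, outdir) -> dict[str, str]:
        """Write metrics, safety cross-tabs, and inference to ``outdir``.

        Output is deterministic: identical inputs reproduce the files
        byte for byte.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "metrics": outdir / "metrics.csv",
            "safety": outdir / "safety.csv",
            "inference": outdir / "inference.json",
        }
        self.metrics.to_csv(paths["metrics"], index=False, float_format="%.10g")
        self.safety.to_csv(paths["safety"], index=False)
        with open(paths["inference"], "w", encoding="utf-8") as fh:
            json.dump(self.inference_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}

    def plot_precision(self, ax=None):
        """Scatter of inclusion rate against DPS, one point per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for group in self.metrics["group"].unique():
            inc = self.metric(group, "inclusion_rate")
            dps = self.metric(group, "dps")
            ax.scatter(dps.estimate, inc.estimate, label=group)
            ax.annotate(group, (dps.estimate, inc.estimate), fontsize=8,
                        xytext=(3, 3), textcoords="offset points")
        ax.set_xlabel("Diagnostic Precision Score (%)")
        ax.set_ylabel("Inclusion rate (%)")
        ax.axvline(0, color="grey", lw=0.5)
        return ax
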