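"""Evidence-synthesis report generation and effect interpretation statistics.

The pooled standardized effect is translated for readers through three
equivalent re-expressions under the standard two-normal model (unit-variance
control and experimental distributions separated by g):

* ``u3``    — Cohen's non-overlap: the percentage of the experimental
  distribution above the control mean, 100*Phi(g).
* ``overlap`` — the overlapping coefficient of the two distributions,
  100*2*Phi(-|g|/2).
* ``prob_superiority`` — the common language effect size: the chance that a
  random experimental score exceeds a random control score, 100*Phi(g/sqrt(2)).

At g = 0.50 these round to 69%, 80% and 64%.

The synthesis report itself has seven fixed sections — overview, disclaimer,
search results, overall summary, detailed report (one forest plot per
outcome x population), references, statistical information — rendered as a
self-contained HTML document plus a machine-readable JSON companion.
Narrative percentages are rounded half-up to integers; tables keep full
precision.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field
from scipy.stats import norm

from .effect_size import EffectEstimate
from .grading import CertaintyRating, EvidenceSummary
from .meta_engine import Exclusion, MetaAnalysisSpec, PooledResult
from .quality_scoring import QualityScores
from .trial_model import CodedTrial

SECTION_ORDER = (
    "overview",
    "disclaimer",
    "search_results",
    "overall_summary",
    "detailed_report",
    "references",
    "statistical_information",
)


def _templates() -> dict:
    ref = importlib.resources.files("cotmeta") / "data" / "report_text.yaml"
    return yaml.safe_load(ref.read_text())


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (narrative convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def u3(g: float) -> float:
    """Percentage of the experimental condition above the control mean."""
    return 100.0 * norm.cdf(g)


def overlap(g: float) -> float:
    """Percentage overlap of two unit-variance normals separated by g."""
    return 100.0 * 2.0 * norm.cdf(-abs(g) / 2.0)


def prob_superiority(g: float) -> float:
    """Probability (in %) that a random experimental score beats a random control score."""
    return 100.0 * norm.cdf(g / math.sqrt(2.0))


def interpretation_triple(g: float) -> tuple[int, int, int]:
    """(U3, overlap, probability of superiority), rounded to integer percent."""
    return (
        round_half_up(u3(g)),
        round_half_up(overlap(g)),
        round_half_up(prob_superiority(g)),
    )


def interpretation_sentence(g: float) -> str:
    """Reader-facing sentence re-expressing a pooled g via the three statistics."""
    a, b, c = interpretation_triple(g)
    return _templates()["interpretation_sentence"].format(
        u3=a, overlap=b, prob_superiority=c
    )


# --------------------------------------------------------------------------
# Report document
# --------------------------------------------------------------------------

class Section(BaseModel):
    key: str
    title: str
    text: str = ""
    tables: dict[str, list[dict]] = Field(default_factory=dict)
    figures: list[str] = Field(default_factory=list)  # file paths relative to the report


class ReportDocument(BaseModel):
    title: str = "Evidence synthesis report"
    sections: list[Section]

    def section(self, key: str) -> Section:
        for s in self.sections:
            if s.key == key:
                return s
        raise KeyError(key)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)

    def to_html(self) -> str:
        parts = [
            "<!DOCTYPE html><html><head><meta charset='utf-8'>",
            f"<title>{self.title}</title>",
            "<style>body{font-family:sans-serif;max-width:60em;margin:auto}"
            "table{border-collapse:collapse}td,th{border:1px solid #999;padding:4px}</style>",
            "</head><body>",
            f"<h1>{self.title}</h1>",
        ]
        for s in self.sections:
            parts.append(f"<h2>{s.title}</h2>")
            if s.text:
                parts.append(f"<p>{s.text}</p>")
            for name, rows in s.tables.items():
                parts.append(f"<h3>{name}</h3>")
                if rows:
                    cols = list(rows[0].keys())
                    parts.append("<table><tr>" + "".join(f"<th>{c}</th>" for c in cols) + "</tr>")
                    for row in rows:
                        parts.append(
                            "<tr>" + "".join(f"<td>{row.get(c, '')}</td>" for c in cols) + "</tr>"
                        )
                    parts.append("</table>")
            for fig in s.figures:
                parts.append(f"<img src='{fig}' style='max-width:100%'>")
        parts.append("</body></html>")
        return "\n".join(parts)


def forest_plot(
    pooled: PooledResult, path: str | Path, title: Optional[str] = None
) -> Path:
    """Forest plot: per-study markers sized by weight, pooled diamond at the bottom."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [e.trial_id for e, _ in pooled.per_study]
    gs = [e.g for e, _ in pooled.per_study]
    los = [e.ci_low for e, _ in pooled.per_study]
    his = [e.ci_high for e, _ in pooled.per_study]
    weights = [w for _, w in pooled.per_study]
    k = len(labels)
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.4 * (k + 2)))
    ys = list(range(k, 0, -1))
    for y_pos, g, lo, hi, w in zip(ys, gs, los, his, weights):
        ax.plot([lo, hi], [y_pos, y_pos], color="k", lw=1)
        ax.plot([g], [y_pos], marker="s", color="k", markersize=4 + 10 * w)
    ax.fill(
        [pooled.ci_low, pooled.mu, pooled.ci_high, pooled.mu],
        [-0.0, 0.25, 0.0, -0.25],
        color="k",
    )
    if pooled.pi_low is not None:
        ax.plot([pooled.pi_low, pooled.pi_high], [-0.7, -0.7], color="k", lw=2)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys + [0])
    ax.set_yticklabels(labels + ["Pooled (RE, HKSJ)"])
    ax.set_xlabel("Hedges' g (positive favors experimental)")
    ax.set_title(title or f"{pooled.outcome} — {pooled.population}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def summary_plot(
    results: Sequence[tuple[PooledResult, CertaintyRating, EvidenceSummary]],
    path: str | Path,
) -> Path:
    """Summary chart: pooled effect and CI per outcome, colored by certainty."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"low": "#c44e52", "moderate": "#dd8452", "high": "#55a868"}
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.5 * len(results)))
    ys = list(range(len(results), 0, -1))
    for y_pos, (pooled, rating, _) in zip(ys, results):
        c = colors[rating.level]
        ax.plot([pooled.ci_low, pooled.ci_high], [y_pos, y_pos], color=c, lw=2)
        ax.plot([pooled.mu], [y_pos], "o", color=c)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{p.outcome} / {p.population}" for p, _, _ in results])
    ax.set_xlabel("Hedges' g with 95% CI (color = certainty)")
    handles = [plt.Line2D([0], [0], color=c, lw=3, label=lvl) for lvl, c in colors.items()]
    ax.legend(handles=handles, loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def build_report(
    spec: MetaAnalysisSpec,
    results: Sequence[tuple[PooledResult, CertaintyRating, EvidenceSummary]],
    trials: Sequence[CodedTrial] = (),
    exclusions: Sequence[Exclusion] = (),
    output_dir: Optional[str | Path] = None,
) -> ReportDocument:
    """Assemble the seven-section synthesis report.

    When ``output_dir`` is given, forest plots and the summary chart are
    written there and referenced from the document; otherwise the document
    is figure-free (content identical, deterministic given inputs).
    """
    tpl = _templates()
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    trials_by_id = {t.trial_id: t for t in trials}
    contributing_ids: list[str] = []
    for pooled, _, _ in results:
        for e, _w in pooled.per_study:
            if e.trial_id not in contributing_ids:
                contributing_ids.append(e.trial_id)

    search_text = (
        f"Scope: populations={spec.populations or 'all'}, "
        f"broad outcomes={spec.broad_outcomes or 'all available'}, "
        f"targets={spec.targets}, time point={spec.time_point!r}. "
        f"{len(results)} outcome/population group(s) met the pooling criteria "
        f"(at least {spec.min_k} studies with usable means and SDs)."
    )
    excl_rows = [e.model_dump(exclude_none=True) for e in exclusions]

    overall = Section(key="overall_summary", title="Overall summary")
    detailed = Section(key="detailed_report", title="Detailed report")
    if results:
        overall.text = (
            "Effects are standardized mean differences (Hedges' g); positive "
            "values favor the experimental condition. Recommendations follow "
            "the certainty of the evidence: strong for high certainty, modest "
            "for moderate certainty, none for low certainty."
        )
        overall.tables["Results and recommendations"] = [
            {
                "outcome": p.outcome,
                "population": p.population,
                "k": p.k,
                "n": p.n_total,
                "g": round(p.mu, 3),
                "ci": f"[{p.ci_low:.3f}, {p.ci_high:.3f}]",
                "certainty": r.level,
                "recommendation": s.recommendation,
            }
            for p, r, s in results
        ]
        if out is not None:
            sp = summary_plot(results, out / "summary_plot.png")
            overall.figures.append(sp.name)
        rows = []
        for pooled, rating, summary in results:
            rows.append(
                {
                    "outcome": pooled.outcome,
                    "population": pooled.population,
                    "k": pooled.k,
                    "n": pooled.n_total,
                    "g": round(pooled.mu, 4),
                    "se_hksj": round(pooled.se_hksj, 4),
                    "ci": f"[{pooled.ci_low:.4f}, {pooled.ci_high:.4f}]",
                    "tau2": round(pooled.tau2, 4),
                    "Q": round(pooled.q, 3),
                    "p_Q": round(pooled.p_q, 4),
                    "I2_pct": round(pooled.i2, 1),
                    "PI": (
                        f"[{pooled.pi_low:.4f}, {pooled.pi_high:.4f}]"
                        if pooled.pi_low is not None else "n/a"
                    ),
                    "interpretation": interpretation_sentence(pooled.mu),
                    "narrative": summary.narrative,
                }
            )
            if out is not None:
                fp = forest_plot(
                    pooled, out / f"forest_{pooled.outcome}_{pooled.population}.png"
                )
                detailed.figures.append(fp.name)
        detailed.tables["Pooled results"] = rows
    else:
        notice = tpl["no_results_notice"].format(min_k=spec.min_k)
        overall.text = notice
        detailed.text = notice
    if excl_rows:
        detailed.tables["Exclusions"] = excl_rows

    references = Section(key="references", title="References")
    references.tables["Included studies"] = [
        {
            "trial_id": tid,
            "citation": _format_citation(trials_by_id[tid]) if tid in trials_by_id else tid,
        }
        for tid in contributing_ids
    ]

    doc = ReportDocument(
        sections=[
            Section(key="overview", title="Overview", text=tpl["overview"].strip()),
            Section(key="disclaimer", title="Disclaimer", text=tpl["disclaimer"].strip()),
            Section(key="search_results", title="Search results", text=search_text),
            overall,
            detailed,
            references,
            Section(
                key="statistical_information",
                title="Statistical information",
                text=tpl["statistical_information"].strip(),
            ),
        ]
    )
    assert tuple(s.key for s in doc.sections) == SECTION_ORDER
    if out is not None:
        (out / "report.html").write_text(doc.to_html())
        (out / "report.json").write_text(doc.to_json())
    return doc


def _format_citation(trial: CodedTrial) -> str:
    c = trial.citation
    authors = ", ".join(c.authors[:3]) + (" et al." if len(c.authors) > 3 else "")
    journal = f" {c.journal}." if c.journal else ""
    doi = f" doi:{c.doi}" if c.doi else ""
    return f"{authors} ({c.year}). {c.title}.{journal}{doi}"


def single_study_page(
    trial: CodedTrial,
    scores: Optional[QualityScores] = None,
    effects: Sequence[EffectEstimate] = (),
) -> ReportDocument:
    """Single-study results page: status, citation, quality table, effect tables, summary."""
    header = Section(
        key="overview",
        title=f"{trial.trial_id} [{trial.status.value}]",
        text=_format_citation(trial),
    )
    quality = Section(key="quality", title="Methodological quality")
    if scores is not None:
        quality.tables["Totals"] = [
            {"PEDro (0-10)": scores.pedro_total, "Jadad (0-5)": scores.jadad_total}
        ]
        quality.tables["PEDro items"] = [
            {"item": k, "satisfied": v} for k, v in scores.pedro_items.items()
        ]
        quality.tables["Jadad items"] = [
            {"item": k, "satisfied": v} for k, v in scores.jadad_items.items()
        ]
        quality.tables["Risk of bias"] = [
            {"domain": k, "rating": v} for k, v in scores.rob_domains.items()
        ]
    effects_section = Section(key="effects", title="Effect sizes")
    if effects:
        effects_section.tables["Effects"] = [
            {
                "measure": e.measure_id,
                "time_point": e.time_point,
                "comparison": f"{e.experimental_arm_id} vs {e.control_arm_id}",
                "g": round(e.g, 4),
                "ci": f"[{e.ci_low:.4f}, {e.ci_high:.4f}]",
                "adjusted": e.adjusted,
            }
            for e in effects
        ]
    else:
        effects_section.text = "Effect size data not available for this study."
    summary = Section(key="summary", title="Plain language summary", text=trial.summary_text)
    return ReportDocument(
        title=f"Study record: {trial.trial_id}",
        sections=[header, quality, effects_section, summary],
    )
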