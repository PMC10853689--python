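"""Automated markdown trial reports.

Two audiences: an overview for the trial manager (worth table, win
probabilities against the leader, attrition, optional tree summary) and a
personalized result sheet per participant. Result sheets are the first
artifact where option names are revealed; everything upstream is blind.
Output is deterministic: equal inputs give identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plackett import PLFit, win_probability
from .pltree import PLTreeNode
from .rankings import TricotResponse, response_to_ranking
from .trial import Project

__all__ = ["ReportBundle", "generate_report"]


@dataclass(frozen=True)
class ReportBundle:
    overview: str
    participant_sheets: dict[int, str]  # package_id -> markdown


def _sorted_options(fit: PLFit) -> list[tuple[str, float]]:
    """Options with normalized worths, descending; alphabetical tie-break."""
    worths = fit.worths
    total = worths.sum()
    pairs = [
        (name, float(w / total)) for name, w in zip(fit.universe, worths)
    ]
    return sorted(pairs, key=lambda p: (-round(p[1], 12), p[0]))


def _tree_summary(node: PLTreeNode, indent: int = 0) -> list[str]:
    pad = "  " * indent
    if node.is_leaf:
        top = _sorted_options(node.fit)[0][0]
        return [f"{pad}- leaf (n={node.n_rankings}): best option {top}"]
    if node.categories is not None:
        cond = f"{node.covariate} in {sorted(node.categories)}"
    else:
        cond = f"{node.covariate} <= {node.threshold:g}"
    lines = [
        f"{pad}- split on {cond} "
        f"(LR={node.lr_statistic:.2f}, adj. p={node.p_value:.4g})"
    ]
    lines += _tree_summary(node.left, indent + 1)
    lines += _tree_summary(node.right, indent + 1)
    return lines


def generate_report(
    project: Project,
    fits: dict[str, PLFit],
    responses: list[TricotResponse],
    tree: PLTreeNode | None = None,
) -> ReportBundle:
    """Build the overview document and one result sheet per participant."""
    if not fits:
        raise ValueError("at least one fitted trait is required")
    design = project.design
    design_options = set(design.option_names)
    for trait, fit in fits.items():
        if set(fit.universe) != design_options:
            raise ValueError(
                f"fit for trait {trait!r} covers {sorted(fit.universe)}, "
                f"design has {sorted(design_options)}"
            )

    by_package: dict[int, dict[str, TricotResponse]] = {}
    for r in responses:
        by_package.setdefault(r.package_id, {})[r.trait] = r
    responders = {
        pid
        for pid, traits in by_package.items()
        if any(r.best is not None or r.worst is not None for r in traits.values())
    }
    n = design.n_packages
    n_resp = len(responders & set(range(1, n + 1)))

    lines = [
        f"# Trial overview: {project.title}",
        "",
        f"Project `{project.project_id}` — {len(design.option_names)} options, "
        f"{n} packages.",
        "",
        f"Responses received from {n_resp} of {n} participants "
        f"({n - n_resp} without data).",
        "",
    ]
    for trait in sorted(fits):
        fit = fits[trait]
        ranked = _sorted_options(fit)
        lines += [f"## Trait: {trait}", "", "| Rank | Option | Worth |", "|---|---|---|"]
        for rank, (name, w) in enumerate(ranked, start=1):
            lines.append(f"| {rank} | {name} | {w:.4f} |")
        leader = ranked[0][0]
        lines += [
            "",
            f"Probability that **{leader}** outperforms each other option:",
            "",
            "| Option | P(leader wins) |",
            "|---|---|",
        ]
        for name, _ in ranked[1:]:
            lines.append(
                f"| {name} | {win_probability(fit, leader, name):.4f} |"
            )
        lines.append("")
    if tree is not None:
        lines += ["## Preference heterogeneity", ""]
        if tree.is_leaf:
            lines.append("No covariate-driven heterogeneity detected (single group).")
        else:
            lines += _tree_summary(tree)
        lines.append("")
    overview = "\n".join(lines)

    primary_trait = sorted(fits)[0]
    trial_rank = {
        name: rank
        for rank, (name, _) in enumerate(_sorted_options(fits[primary_trait]), 1)
    }

    sheets: dict[int, str] = {}
    for pkg in design.packages:
        s = [
            f"# Result sheet — package {pkg.package_id}",
            "",
            f"Trial: {project.title}",
            "",
            "Your package contained (positions A, B, C):",
            "",
        ]
        for pos, name in zip("ABC", pkg.options):
            s.append(
                f"- **{pos}**: {name} (ranked #{trial_rank[name]} "
                f"trial-wide for {primary_trait})"
            )
        s.append("")
        resp = by_package.get(pkg.package_id, {}).get(primary_trait)
        ranking = (
            response_to_ranking(resp, design) if resp is not None else None
        )
        if ranking is None:
            s.append(f"Your ranking for {primary_trait}: no data recorded.")
        else:
            pretty = " > ".join(
                "(" + " = ".join(g) + ")" if len(g) > 1 else g[0]
                for g in ranking.groups
            )
            s.append(f"Your ranking for {primary_trait}: {pretty}")
        s.append("")
        sheets[pkg.package_id] = "\n".join(s)

    return ReportBundle(overview=overview, participant_sheets=sheets)
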