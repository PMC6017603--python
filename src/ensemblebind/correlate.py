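"""Correlation of ensemble pocket availability with equilibrium binding,
plus the pipeline's summary report.

With a handful of ligands (typically n = 4) asymptotic correlation p-values
are meaningless, so inference is by exact permutation: all n! pairings are
enumerated (n ≤ 8) and the one-sided p is the fraction of pairings whose
statistic is at least the observed one. The smallest achievable p is
therefore 1/n! — at n = 4 no association, however perfect, can beat
p = 1/24 ≈ 0.0417.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .spr import CompetitionResult, FitResult

EXACT_ENUMERATION_MAX_N = 8
MC_PERMUTATIONS = 20000


@dataclass
class CorrelationResult:
    """Pearson and Spearman association with exact permutation p-values."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    exact: bool
    p_floor: float
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p_one_sided": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p_one_sided": self.spearman_p,
            "exact_enumeration": self.exact,
            "smallest_achievable_p": self.p_floor,
            "notes": self.notes,
        }


def _perm_p(x: np.ndarray, y: np.ndarray, stat, observed: float, seed: int) -> tuple[float, bool]:
    n = x.size
    if n <= EXACT_ENUMERATION_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if stat(x, y[list(perm)]) >= observed - 1e-12:
                count += 1
        return count / total, True
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation always counts
    for _ in range(MC_PERMUTATIONS):
        if stat(x, rng.permutation(y)) >= observed - 1e-12:
            count += 1
    return count / (MC_PERMUTATIONS + 1), False


def correlate(
    propensities: Mapping[str, float],
    binding_values: Mapping[str, float],
    seed: int = 0,
) -> CorrelationResult:
    """Correlate per-ligand pocket availability with per-ligand binding (RU).

    Ligand labels must match between the two mappings; both vectors must be
    non-constant. One-sided p-values test for positive association.
    """
    labels = sorted(propensities)
    if sorted(binding_values) != labels:
        only_a = sorted(set(propensities) - set(binding_values))
        only_b = sorted(set(binding_values) - set(propensities))
        raise AnalysisError(f"ligand label mismatch: propensity-only {only_a}, binding-only {only_b}")
    if len(labels) < 3:
        raise AnalysisError(f"need at least 3 ligands, have {len(labels)}")
    x = np.array([float(propensities[k]) for k in labels])
    y = np.array([float(binding_values[k]) for k in labels])
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AnalysisError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined for a constant vector")

    def pearson(a, b):
        return float(stats.pearsonr(a, b).statistic)

    def spearman(a, b):
        return float(stats.spearmanr(a, b).statistic)

    r = pearson(x, y)
    rho = spearman(x, y)
    p_r, exact = _perm_p(x, y, pearson, r, seed)
    p_rho, _ = _perm_p(x, y, spearman, rho, seed)
    n = len(labels)
    floor = 1.0 / float(math.factorial(n)) if exact else 1.0 / (MC_PERMUTATIONS + 1)
    return CorrelationResult(
        n=n,
        pearson_r=r,
        pearson_p=p_r,
        spearman_rho=rho,
        spearman_p=p_rho,
        exact=exact,
        p_floor=floor,
        notes=(
            f"one-sided exact permutation over all {n}! pairings"
            if exact
            else f"one-sided Monte-Carlo permutation ({MC_PERMUTATIONS} draws, seed {seed})"
        ),
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


def build_report(
    cluster_summary: Mapping | None,
    propensity_results: Mapping[str, object],
    fit_results: Mapping[str, FitResult | None],
    correlation: CorrelationResult | None,
    competition_results: Mapping[str, CompetitionResult] | None = None,
    warnings: list[str] | None = None,
) -> dict:
    """Assemble the pipeline's JSON-serialisable summary report.

    Ligands whose affinity is not determinable (``fit_results[label] is
    None``) are listed as non-binders and excluded from the correlation
    block; ligands present in one block but not another land under
    ``unmatched`` with a warning rather than an error.
    """
    warnings = list(warnings or [])
    prop_labels = set(propensity_results)
    spr_labels = set(fit_results)
    unmatched = sorted(prop_labels ^ spr_labels)
    if unmatched:
        warnings.append(f"ligands present in only one analysis block: {', '.join(unmatched)}")

    ligands = {}
    for label in sorted(prop_labels | spr_labels):
        entry: dict = {}
        pr = propensity_results.get(label)
        if pr is not None:
            entry["propensity"] = getattr(pr, "propensity", pr)
            entry["n_frames"] = getattr(pr, "n_frames", None)
        fit = fit_results.get(label)
        if fit is None and label in spr_labels:
            entry["Kd_uM"] = "n.d."
            entry["non_binder"] = True
        elif fit is not None:
            entry["Kd_uM"] = fit.Kd_M * 1e6
            entry["Bmax_RU"] = fit.Bmax_RU
            entry["saturable"] = fit.saturable
            entry["presumed"] = fit.presumed
        if competition_results and label in competition_results:
            entry["competition_percent_change"] = competition_results[label].percent_change
        ligands[label] = entry

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "clusters": dict(cluster_summary) if cluster_summary else None,
        "ligands": ligands,
        "non_binders": sorted(l for l, f in fit_results.items() if f is None),
        "unmatched": unmatched,
        "correlation": correlation.as_dict() if correlation is not None else {"available": False},
        "warnings": warnings,
    }
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    lines = [f"ensemblebind report (schema {report['schema_version']})", ""]
    if report.get("clusters"):
        cl = report["clusters"]
        occ = ", ".join(f"{o * 100:.1f}%" for o in cl.get("occupancies", []))
        lines.append(f"Conformational clusters: {cl.get('n_clusters')} (occupancies {occ}; "
                     f"representative frame {cl.get('representative_frame')})")
        lines.append("")
    lines.append(f"{'ligand':<12} {'propensity':>10} {'Kd (uM)':>10} {'Bmax (RU)':>10} {'flags':>10}")
    for label, e in report["ligands"].items():
        prop = e.get("propensity")
        kd = e.get("Kd_uM")
        bmax = e.get("Bmax_RU")
        flags = "n.d." if e.get("non_binder") else ("presumed" if e.get("presumed") else "")
        prop_s = "-" if prop is None else f"{prop:.3f}"
        kd_s = f"{kd:.1f}" if isinstance(kd, float) else str(kd or "-")
        bmax_s = f"{bmax:.1f}" if isinstance(bmax, float) else "-"
        lines.append(f"{label:<12} {prop_s:>10} {kd_s:>10} {bmax_s:>10} {flags:>10}")
    lines.append("")
    corr = report["correlation"]
    if corr.get("available") is False:
        lines.append("Correlation: unavailable (missing propensity or binding block)")
    else:
        lines.append(
            f"Correlation (n={corr['n']}): Pearson r={corr['pearson_r']:.3f} "
            f"(p={corr['pearson_p_one_sided']:.4f}), Spearman rho={corr['spearman_rho']:.3f} "
            f"(p={corr['spearman_p_one_sided']:.4f}); smallest achievable p="
            f"{corr['smallest_achievable_p']:.4f}"
        )
    for w in report["warnings"]:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
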