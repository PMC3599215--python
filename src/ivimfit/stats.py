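"""Per-lesion summaries and cohort-level comparison statistics.

Each lesion ROI is reduced to summary statistics (median, mean, SD, range)
of a parameter map over its QC-passing voxels; cohort analysis then operates
on the per-lesion medians, mirroring standard practice for ROI-based DWI
studies.  Scheme pairs are compared by percent deviation of central values,
the two-sided Wilcoxon signed-rank test (exact null for n <= 25, normal
approximation above; zero differences dropped), and tie-corrected Spearman
rank correlation.  No multiple-testing correction is applied by default (a
Holm option exists), with the significance level conventionally at 5 %.

The percent deviation between central values a and b is 100*(a-b)/b, which
satisfies the reciprocal identity (1 + dev(a,b)/100)*(1 + dev(b,a)/100) = 1.

Because "deviation of median values" between two schemes is ambiguous at the
1 % level, both conventions are implemented: ``method="group_median"``
(default) compares cohort medians of per-lesion medians; ``method="per_lesion"``
takes the cohort median of per-lesion deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .fitting import ParameterMap
from .schemes import builtin_schemes

__all__ = [
    "LesionSummary",
    "DeviationMatrix",
    "summarize_roi",
    "deviation",
    "paired_compare",
    "rank_correlation",
    "deviation_matrix",
    "cohort_report",
    "write_report",
]

log = logging.getLogger(__name__)

#: Display scale for diffusivities in reports (the 1e-3 mm^2/s convention).
DISPLAY_SCALE = 1e3


@dataclass(frozen=True)
class LesionSummary:
    """Summary of one parameter map over one lesion's QC-passing voxels."""

    lesion_id: int
    scheme_id: str
    parameter: str
    median: float
    mean: float
    sd: float
    min: float
    max: float
    n_voxels_used: int

    @property
    def usable(self) -> bool:
        return self.n_voxels_used >= 1


@dataclass
class DeviationMatrix:
    """Pairwise percent deviations and paired-test p-values between schemes."""

    scheme_ids: list
    deviations: np.ndarray  # (k, k) percent
    p_values: np.ndarray  # (k, k) Wilcoxon two-sided

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.deviations, index=self.scheme_ids, columns=self.scheme_ids
        )


def summarize_roi(pmap: ParameterMap, mask, lesion_id: int = 0) -> LesionSummary:
    """Reduce one parameter map over one ROI to summary statistics.

    Only voxels inside the mask that also pass QC contribute.  An empty
    intersection yields an unusable summary (``n_voxels_used = 0``, nan
    statistics) with a logged warning; cohort tests skip such lesions.
    """
    sel = np.asarray(mask, dtype=bool) & pmap.qc_mask
    vals = pmap.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.warning(
            "lesion %s has no QC-passing voxels for %s/%s; flagged unusable",
            lesion_id, pmap.scheme_id, pmap.parameter,
        )
        nan = float("nan")
        return LesionSummary(lesion_id, pmap.scheme_id, pmap.parameter,
                             nan, nan, nan, nan, nan, 0)
    return LesionSummary(
        lesion_id=lesion_id,
        scheme_id=pmap.scheme_id,
        parameter=pmap.parameter,
        median=float(np.median(vals)),
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        n_voxels_used=int(vals.size),
    )


def deviation(a: float, b: float) -> float:
    """Percent deviation of ``a`` from reference ``b``: 100*(a-b)/b.

    A zero reference makes the deviation undefined; nan is returned and a
    warning logged.
    """
    if b == 0:
        log.warning("deviation undefined for zero reference value")
        return float("nan")
    return 100.0 * (a - b) / b


def paired_compare(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-lesion medians.

    Zero differences are dropped (Wilcoxon's convention); if every pair is
    tied the test carries no evidence and p = 1 is returned by convention.
    The exact null distribution is used for n <= 25 (midranks under ties),
    the normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError(f"need >= 5 pairs, got {x.size}")
    diff = x - y
    diff = diff[diff != 0.0]
    if diff.size == 0:
        log.info("all paired differences are zero; p = 1 by convention")
        return 1.0
    method = "exact" if diff.size <= 25 else "approx"
    res = sps.wilcoxon(diff, alternative="two-sided", method=method)
    return float(res.pvalue)


def rank_correlation(x, y):
    """Tie-corrected Spearman rank correlation ``(rho, p)`` (two-sided).

    Constant input makes rho undefined; ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError(f"need >= 5 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("rank correlation undefined for constant input")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _median_table(summaries) -> pd.DataFrame:
    """Per-lesion medians as a lesion x (scheme, parameter) table."""
    rows = [
        {
            "lesion_id": s.lesion_id,
            "key": s.scheme_id if s.parameter in ("adc", "d") else
                   f"{s.scheme_id}:{s.parameter}",
            "median": s.median,
        }
        for s in summaries
        if s.usable
    ]
    if not rows:
        raise ConfigurationError("no usable lesion summaries")
    return pd.DataFrame(rows).pivot(index="lesion_id", columns="key",
                                    values="median")


def deviation_matrix(summaries, scheme_keys=None,
                     method: str = "group_median") -> DeviationMatrix:
    """Pairwise percent-deviation and Wilcoxon p-value matrices.

    ``summaries`` are per-lesion summaries of the diffusivity maps (ADC per
    mono scheme, D for the biexp scheme).  ``scheme_keys`` selects and orders
    the columns (default: clinical schemes B0-B5 plus B0_biexp, the
    comparison of clinical interest).

    ``method="group_median"`` computes deviations from cohort medians of the
    per-lesion medians, so the reciprocal identity holds exactly;
    ``method="per_lesion"`` aggregates per-lesion deviations by their cohort
    median (the two conventions differ at the percent level).
    """
    table = _median_table(summaries)
    if scheme_keys is None:
        scheme_keys = [s.id for s in builtin_schemes()
                       if s.clinical or s.model == "biexp"]
    missing = [k for k in scheme_keys if k not in table.columns]
    if missing:
        raise ConfigurationError(f"no summaries for scheme(s) {missing}")
    if method not in ("group_median", "per_lesion"):
        raise ConfigurationError(f"unknown deviation method {method!r}")

    k = len(scheme_keys)
    dev = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i, a in enumerate(scheme_keys):
        for j, b in enumerate(scheme_keys):
            if i == j:
                continue
            xa = table[a].dropna()
            xb = table[b].dropna()
            common = xa.index.intersection(xb.index)
            xa, xb = xa[common].to_numpy(), xb[common].to_numpy()
            if method == "group_median":
                dev[i, j] = deviation(float(np.median(xa)), float(np.median(xb)))
            else:
                dev[i, j] = float(np.median(
                    [deviation(va, vb) for va, vb in zip(xa, xb) if vb != 0]
                ))
            pvals[i, j] = paired_compare(xa, xb)
    return DeviationMatrix(list(scheme_keys), dev, pvals)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def holm_correction(pvals):
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    prev = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        adj[idx] = prev = max(prev, min(1.0, (m - rank) * p[idx]))
    return adj


def cohort_report(summaries, qc_reports=None, deviation_method="group_median",
                  deviation_keys=None) -> dict:
    """Assemble the cohort tables.

    Returns a dict with:

    - ``descriptives``: one row per scheme/parameter with mean +/- SD, median
      and range of the per-lesion medians, diffusivities rendered in
      1e-3 mm^2/s (the ``units`` column says so);
    - ``deviation``: percent-deviation matrix with significance stars;
    - ``deviation_p``: raw p-value matrix;
    - ``correlation``: Spearman rho (and p) of each scheme's per-lesion
      medians against the biexponential D;
    - ``qc``: per-model acceptance fractions when ``qc_reports`` (a mapping
      scheme_id -> per-lesion pass fractions) is given.

    Row/column order follows the scheme registry.  The report is a pure
    function of the summaries: identical inputs reproduce it bit-exactly.
    """
    order = {s.id: i for i, s in enumerate(builtin_schemes())}
    diffusivity = [s for s in summaries if s.parameter in ("adc", "d")]
    other = [s for s in summaries if s.parameter in ("d_star", "fp")]

    def _rows(subset):
        rows = []
        keys = sorted(
            {(s.scheme_id, s.parameter) for s in subset},
            key=lambda k: (order.get(k[0], 99), k[1]),
        )
        for scheme_id, param in keys:
            med = np.array([s.median for s in subset
                            if s.scheme_id == scheme_id and s.parameter == param
                            and s.usable])
            if med.size == 0:
                continue
            scale = DISPLAY_SCALE if param in ("adc", "d", "d_star") else 1.0
            units = "x10^-3 mm^2/s" if param in ("adc", "d", "d_star") else (
                "fraction" if param == "fp" else "a.u.")
            rows.append({
                "scheme": scheme_id,
                "parameter": param,
                "n_lesions": int(med.size),
                "mean": float(np.mean(med) * scale),
                "sd": float(np.std(med, ddof=1) * scale) if med.size > 1 else 0.0,
                "median": float(np.median(med) * scale),
                "min": float(np.min(med) * scale),
                "max": float(np.max(med) * scale),
                "units": units,
            })
        return rows

    descriptives = pd.DataFrame(_rows(diffusivity) + _rows(other))

    report = {"descriptives": descriptives}
    try:
        dm = deviation_matrix(diffusivity, scheme_keys=deviation_keys,
                              method=deviation_method)
    except ConfigurationError:
        dm = None
    if dm is not None and len(dm.scheme_ids) >= 2:
        starred = pd.DataFrame(
            [[f"{dm.deviations[i, j]:.1f}{_stars(dm.p_values[i, j])}"
              if i != j else "0"
              for j in range(len(dm.scheme_ids))]
             for i in range(len(dm.scheme_ids))],
            index=dm.scheme_ids, columns=dm.scheme_ids,
        )
        report["deviation"] = starred
        report["deviation_p"] = pd.DataFrame(
            dm.p_values, index=dm.scheme_ids, columns=dm.scheme_ids
        )
        report["deviation_matrix"] = dm

        table = _median_table(diffusivity)
        biexp_key = next((s.id for s in builtin_schemes() if s.model == "biexp"),
                         None)
        if biexp_key in table.columns:
            corr_rows = []
            for key in dm.scheme_ids:
                if key == biexp_key:
                    corr_rows.append({"scheme": key, "rho": 1.0, "p": 0.0})
                    continue
                xa = table[key].dropna()
                xb = table[biexp_key].dropna()
                common = xa.index.intersection(xb.index)
                rho, p = rank_correlation(xa[common], xb[common])
                corr_rows.append({"scheme": key, "rho": rho, "p": p})
            report["correlation"] = pd.DataFrame(corr_rows)
    else:
        report["deviation"] = pd.DataFrame()
        report["deviation_p"] = pd.DataFrame()

    if qc_reports:
        qc_rows = []
        for scheme_id, fracs in qc_reports.items():
            fr = np.asarray(list(fracs), dtype=float)
            qc_rows.append({
                "scheme": scheme_id,
                "mean_fraction_pass": float(np.mean(fr)),
                "sd_fraction_pass": float(np.std(fr, ddof=1)) if fr.size > 1 else 0.0,
                "min_fraction_pass": float(np.min(fr)),
                "max_fraction_pass": float(np.max(fr)),
            })
        report["qc"] = pd.DataFrame(qc_rows)
    return report


def _df_to_markdown(df: pd.DataFrame, floatfmt="{:.3g}") -> str:
    if df.empty:
        return "(empty)\n"
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(lambda v: floatfmt.format(v))
    if show.index.name or not isinstance(show.index, pd.RangeIndex):
        show = show.reset_index()
    header = "| " + " | ".join(str(c) for c in show.columns) + " |"
    sep = "|" + "|".join([" --- "] * len(show.columns)) + "|"
    body = "\n".join(
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in show.itertuples(index=False)
    )
    return "\n".join([header, sep, body]) + "\n"


def write_report(report: dict, outdir) -> None:
    """Write the cohort report as CSV + JSON per table and one Markdown file."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    md = ["# Cohort report", ""]
    titles = {
        "descriptives": "Per-scheme descriptives of per-lesion medians",
        "deviation": "Pairwise percent deviation (stars: * p<0.05, ** p<0.01, *** p<0.001)",
        "deviation_p": "Wilcoxon signed-rank p-values",
        "correlation": "Spearman correlation against biexponential D",
        "qc": "QC acceptance fraction per scheme (across lesions)",
    }
    for key in ("descriptives", "deviation", "deviation_p", "correlation", "qc"):
        df = report.get(key)
        if df is None or not isinstance(df, pd.DataFrame):
            continue
        df.to_csv(outdir / f"{key}.csv")
        df.to_json(outdir / f"{key}.json", orient="split", indent=2)
        md += [f"## {titles[key]}", "", _df_to_markdown(df), ""]
    (outdir / "report.md").write_text("\n".join(md))
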