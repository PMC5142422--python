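"""Readers and writers: paired-rating CSV, custom weight CSV, reports.

The pairs dialect is a UTF-8 comma-separated file with header
``period,rater1,rater2`` and one row per jointly observed interaction.
Reports are written as JSON (full-precision machine fields plus 2-dp
display strings, stable key order) or as a TSV grid with one row per
weighting scheme; forest data (one row per period plus pooled rows) is a
separate TSV suitable for external plotting.
"""

from __future__ import annotations

import csv
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kappa import KappaEstimate
from .meta import MetaResult, StudyReport
from .weights import CategoryScale, QUIS_SCALE, WeightMatrix, validate_weights

__all__ = [
    "read_pairs",
    "write_pairs",
    "weight_matrix_from_csv",
    "write_weight_csv",
    "report_to_dict",
    "write_report",
    "write_forest",
    "round2",
    "fmt2",
    "PairsFormatError",
    "InvalidWeightsError",
]

REQUIRED_COLUMNS = ("period", "rater1", "rater2")


class PairsFormatError(ValueError):
    """Malformed paired-ratings file; message lists offending line numbers."""


class InvalidWeightsError(ValueError):
    """User-supplied weight matrix violates the weight-matrix contract."""


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def fmt2(x: float | None) -> str:
    return "" if x is None else f"{round2(x):.2f}"


def read_pairs(
    path: str | Path,
    scale: CategoryScale = QUIS_SCALE,
) -> dict[str, list[tuple[str, str]]]:
    """Read per-period rating pairs, preserving period order of appearance.

    Raises
    ------
    PairsFormatError
        On a missing/short header, short rows, or labels not on ``scale``;
        every offending line is named by number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PairsFormatError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise PairsFormatError(
                f"{path}: header {header} is missing column(s) {missing}"
            )
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        need = max(idx.values()) + 1

        pairs: dict[str, list[tuple[str, str]]] = {}
        problems: list[str] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < need:
                problems.append(f"line {line_no}: expected {need} fields, "
                                f"got {len(row)}")
                continue
            period = row[idx["period"]].strip()
            a = row[idx["rater1"]].strip()
            b = row[idx["rater2"]].strip()
            bad = [lab for lab in (a, b) if lab not in scale.labels]
            if bad:
                problems.append(
                    f"line {line_no}: unknown label(s) {bad}; scale is "
                    f"{list(scale.labels)}"
                )
                continue
            pairs.setdefault(period, []).append((a, b))
        if problems:
            raise PairsFormatError(
                f"{path}: {len(problems)} malformed row(s):\n  "
                + "\n  ".join(problems)
            )
    if not pairs:
        raise PairsFormatError(f"{path}: no data rows")
    return pairs


def write_pairs(
    pairs_by_period: Mapping[str, Sequence[tuple[str, str]]],
    path: str | Path,
) -> None:
    """Write per-period rating pairs in the dialect :func:`read_pairs` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for period, pairs in pairs_by_period.items():
            for a, b in pairs:
                writer.writerow([period, a, b])


def weight_matrix_from_csv(path: str | Path,
                           name: str | None = None) -> WeightMatrix:
    """Load a custom k x k weight matrix from CSV.

    The header row gives the k category labels (highest-ranked first); each
    of the k following rows gives that row category's weights.  The matrix
    must be symmetric with unit diagonal and entries in [0, 1].
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise InvalidWeightsError(f"{path}: file is empty")
    labels = tuple(c.strip() for c in rows[0])
    k = len(labels)
    if len(rows) != k + 1:
        raise InvalidWeightsError(
            f"{path}: expected {k} weight rows after the header, got "
            f"{len(rows) - 1}"
        )
    try:
        w = np.array([[float(c) for c in row[:k]] for row in rows[1:]])
    except ValueError as exc:
        raise InvalidWeightsError(f"{path}: non-numeric weight: {exc}") from None
    if w.shape != (k, k):
        raise InvalidWeightsError(f"{path}: expected {k} columns per row")
    W = WeightMatrix(CategoryScale(labels), w,
                     name=name or path.stem)
    violations = validate_weights(W, atol=1e-12)
    if violations:
        raise InvalidWeightsError(
            f"{path}: invalid weight matrix:\n  " + "\n  ".join(violations)
        )
    return W


def write_weight_csv(W: WeightMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(W.scale.labels)
        for row in np.asarray(W.w):
            writer.writerow([f"{x:g}" for x in row])


def _estimate_dict(est: KappaEstimate) -> dict:
    return {
        "kappa": est.kappa,
        "kappa_2dp": fmt2(est.kappa),
        "po_w": est.po_w,
        "pe_w": est.pe_w,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "ci_2dp": f"({fmt2(est.ci_low)}, {fmt2(est.ci_high)})",
        "alpha": est.alpha,
        "n": est.n,
    }


def _meta_dict(res: MetaResult | None) -> dict | None:
    if res is None:
        return None
    out = {
        "method": res.method,
        "estimate": res.estimate,
        "estimate_2dp": fmt2(res.estimate),
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "ci_2dp": f"({fmt2(res.ci_low)}, {fmt2(res.ci_high)})",
        "alpha": res.alpha,
        "g": res.g,
    }
    if res.chi2_het is not None:
        out["chi2_het"] = res.chi2_het
        out["chi2_het_2dp"] = fmt2(res.chi2_het)
        out["df"] = res.df
        out["het_p"] = res.het_p
    if res.tau2 is not None:
        out["tau2"] = res.tau2
    if res.meta_weights is not None:
        out["pct_weights"] = dict(res.meta_weights)
    return out


def report_to_dict(report: StudyReport) -> dict:
    """JSON-ready view of a study report (stable key order)."""
    return {
        "scheme": report.scheme,
        "alpha": report.alpha,
        "scale": list(report.scale.labels),
        "n_total": report.collapsed_table.n,
        "g_used": len(report.period_estimates),
        "excluded_periods": dict(report.excluded),
        "messages": dict(report.messages),
        "collapsed": _estimate_dict(report.collapsed),
        "fixed": _meta_dict(report.fixed),
        "random": _meta_dict(report.random),
        "averaged": _meta_dict(report.averaged),
        "periods": {
            pid: _estimate_dict(est)
            for pid, est in report.period_estimates.items()
        },
    }


def _grid_rows(reports: Sequence[StudyReport]) -> list[dict[str, str]]:
    rows = []
    for rep in reports:
        row = {
            "scheme": rep.scheme,
            "collapsed": fmt2(rep.collapsed.kappa),
            "collapsed_ci": f"({fmt2(rep.collapsed.ci_low)}, "
                            f"{fmt2(rep.collapsed.ci_high)})",
        }
        for key in ("fixed", "random", "averaged"):
            res: MetaResult | None = getattr(rep, key)
            row[key] = fmt2(res.estimate) if res else ""
            row[f"{key}_ci"] = (
                f"({fmt2(res.ci_low)}, {fmt2(res.ci_high)})" if res else ""
            )
        row["chi2_het"] = fmt2(rep.fixed.chi2_het) if rep.fixed else ""
        row["tau2"] = (
            f"{rep.random.tau2:.4f}"
            if rep.random and rep.random.tau2 is not None else ""
        )
        rows.append(row)
    return rows


_GRID_COLUMNS = ("scheme", "collapsed", "collapsed_ci", "fixed", "fixed_ci",
                 "chi2_het", "random", "random_ci", "tau2",
                 "averaged", "averaged_ci")


def write_report(
    reports: StudyReport | Sequence[StudyReport],
    path: str | Path,
    fmt: str = "json",
) -> None:
    """Write one or more scheme reports as JSON or as a TSV grid.

    The TSV grid has one row per weighting scheme with the collapsed,
    fixed, heterogeneity, random and averaged columns; the JSON carries
    full-precision fields alongside the 2-dp display values.
    """
    if isinstance(reports, StudyReport):
        reports = [reports]
    path = Path(path)
    if fmt == "json":
        payload = {
            "alpha": reports[0].alpha,
            "schemes": {rep.scheme: report_to_dict(rep) for rep in reports},
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif fmt == "tsv":
        lines = ["\t".join(_GRID_COLUMNS)]
        for row in _grid_rows(reports):
            lines.append("\t".join(row[c] for c in _GRID_COLUMNS))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}; use 'json' or 'tsv'")


def write_forest(report: StudyReport, path: str | Path) -> None:
    """Export forest-plot data: per-period rows plus pooled summary rows."""
    path = Path(path)
    header = ("row", "n", "kappa_wm", "se", "ci_low", "ci_high",
              "pct_weight_fixed", "pct_weight_random")
    lines = ["\t".join(header)]

    def _fmt_weight(res: MetaResult | None, pid: str) -> str:
        if res is None or res.meta_weights is None:
            return ""
        return f"{res.meta_weights.get(pid, 0.0):.2f}"

    for pid, est in report.period_estimates.items():
        lines.append("\t".join([
            pid, str(est.n), f"{est.kappa:.6f}", f"{est.se:.6f}",
            f"{est.ci_low:.6f}", f"{est.ci_high:.6f}",
            _fmt_weight(report.fixed, pid), _fmt_weight(report.random, pid),
        ]))
    for label, res in (("I-V overall (fixed)", report.fixed),
                       ("D+L overall (random)", report.random),
                       ("simple average", report.averaged)):
        if res is None:
            continue
        lines.append("\t".join([
            label, str(report.collapsed_table.n), f"{res.estimate:.6f}",
            f"{res.se:.6f}", f"{res.ci_low:.6f}", f"{res.ci_high:.6f}",
            "100.00" if res.method == "fixed" else "",
            "100.00" if res.method == "random" else "",
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
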