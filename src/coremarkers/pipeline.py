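"""End-to-end run: read inputs, binarize, select core markers, report.

``run_pipeline`` wires the stages together: expression TSV -> labels (direct
R/NR file, a clinical-category file plus a rule, or a survival file through
the two-mode split) -> leave-one-out core-marker selection -> suitability
report. The accompanying :class:`RunReport` records input digests, the
effective configuration, per-stage timings and coded warnings, so a run can
be audited and reproduced. All output orderings are stable, making repeated
runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

from .dataset import read_expression, read_labels_table, read_survival_table
from .errors import CoreMarkersError, DataError
from .response import (
    BinaryLabels,
    SurvivalSeries,
    fit_survival_split,
    labels_from_survival,
    binarize_response,
)
from .selection import (
    MIN_RECOMMENDED_N,
    CoreMarkerResult,
    SelectionConfig,
    SuitabilityReport,
    assess_suitability,
    balance_ratio,
    loo_core_markers,
)

__all__ = ["RunReport", "run_pipeline", "result_to_json"]

LOW_BALANCE = 0.1  # warn when the minority class drops below this fraction


@dataclass
class RunReport:
    """Audit trail of one pipeline run."""

    input_digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[dict[str, str]] = field(default_factory=list)

    def warn(self, code: str, message: str) -> None:
        self.warnings.append({"code": code, "message": message})

    def to_dict(self) -> dict:
        return {
            "input_digests": self.input_digests,
            "config": self.config,
            "timings": {k: round(v, 4) for k, v in self.timings.items()},
            "warnings": self.warnings,
        }


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(report: RunReport, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report.timings[name] = time.perf_counter() - self.t0
            if isinstance(exc, CoreMarkersError) and not getattr(exc, "_staged", False):
                exc._staged = True
                exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            return False

    return _Timer()


def run_pipeline(
    expr_path: str | Path,
    labels_path: str | Path | None = None,
    survival_path: str | Path | None = None,
    rule_id: str | None = None,
    config: SelectionConfig | None = None,
    min_separation: float = 1.0,
) -> tuple[CoreMarkerResult, SuitabilityReport, RunReport]:
    """Run the full core-marker workflow on files.

    Exactly one of ``labels_path`` / ``survival_path`` must be given. A
    labels file holding literal R/NR values is used directly; any other
    categories require ``rule_id``. A survival file is binarized through the
    fitted two-mode threshold first.
    """
    if (labels_path is None) == (survival_path is None):
        raise DataError("provide exactly one of labels_path or survival_path")
    config = config or SelectionConfig()
    report = RunReport()
    report.config = {
        "q": config.q,
        "min_core_genes": config.min_core_genes,
        "rule_id": rule_id,
        "min_separation": min_separation,
    }

    with _stage(report, "read_expression"):
        dataset = read_expression(expr_path)
        report.input_digests[str(expr_path)] = _digest(expr_path)

    with _stage(report, "labels"):
        if survival_path is not None:
            report.input_digests[str(survival_path)] = _digest(survival_path)
            surv_series = read_survival_table(survival_path)
            series = SurvivalSeries(
                surv_series.index.to_numpy(dtype=str), surv_series.to_numpy()
            )
            threshold = fit_survival_split(series, min_separation=min_separation)
            labels = labels_from_survival(series, threshold)
            report.config["survival_threshold_days"] = threshold.threshold
        else:
            report.input_digests[str(labels_path)] = _digest(labels_path)
            raw = read_labels_table(labels_path)
            values = set(raw.unique())
            if values <= {"R", "NR"}:
                labels = BinaryLabels(
                    raw.index.to_numpy(dtype=str),
                    raw.to_numpy(dtype=str),
                    provenance="file",
                )
            else:
                if rule_id is None:
                    raise DataError(
                        "labels file holds clinical categories "
                        f"({sorted(values)[:4]}...); a --rule is required"
                    )
                labels = binarize_response(raw, rule_id)

    with _stage(report, "diagnostics"):
        n = dataset.n_samples
        if n < MIN_RECOMMENDED_N:
            report.warn(
                "SMALL_N",
                f"cohort has {n} cases, below the inclusion criterion of at "
                f"least {MIN_RECOMMENDED_N} expression profiles",
            )
        ratio = balance_ratio(labels)
        if ratio < LOW_BALANCE:
            report.warn(
                "IMBALANCED",
                f"minority class fraction {ratio:.3f} below {LOW_BALANCE}; "
                "core marker sets from poorly balanced cohorts are unreliable",
            )

    with _stage(report, "loo_core_markers"):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)  # SMALL_N already coded
            result = loo_core_markers(dataset, labels, config)

    with _stage(report, "assess_suitability"):
        suitability = assess_suitability(result, config)

    return result, suitability, report


def result_to_json(
    result: CoreMarkerResult,
    suitability: SuitabilityReport,
    report: RunReport | None = None,
    verbose_folds: bool = False,
) -> str:
    """Serialize a run outcome to stable, byte-reproducible JSON."""
    payload: dict = {
        "core_genes": result.sorted_core_genes(),
        "n_core": result.n_core,
        "suitable": result.suitable,
        "config": {"q": result.config.q, "min_core_genes": result.config.min_core_genes},
        "n_responders": result.n_responders,
        "n_nonresponders": result.n_nonresponders,
        "balance": suitability.balance,
        "per_fold_sizes": dict(sorted(suitability.per_fold_sizes.items())),
    }
    if verbose_folds:
        payload["per_fold_top"] = {
            sid: sorted(genes) for sid, genes in sorted(result.per_fold_top.items())
        }
    if report is not None:
        payload["run_report"] = report.to_dict()
    return json.dumps(payload, indent=2, sort_keys=True)
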