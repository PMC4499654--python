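"""CSV/TSV readers and writers, run configuration, pipeline dispatch.

CSV conventions: comma separator, ``.`` decimal, optional header
(auto-detected).  A single-column file is one series; a multi-column file
holds one series per row, with optional leading ``id`` and ``label``
(healthy/sick/unknown) columns, which are recognized by being non-numeric.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classifiers, lflf, synth
from .bp_core import TrainingConfig, save_model, train
from .classifiers import DiagnosisPolicy, EcgSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "write_single_series_csv",
    "write_verdicts_tsv",
    "write_decomposition_csv",
    "RunConfig",
    "run_pipeline",
]

_LABELS = ("healthy", "sick", "unknown")


def _parse_cell(cell: str, row: int, col: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"non-numeric cell {cell!r} at row {row}, column {col}"
        ) from None


def read_series_csv(path: str | Path) -> list[EcgSeries]:
    """Read one or many series from a CSV file.

    Row and column numbers in error messages are 1-based file coordinates.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        raw_rows = [(i + 1, row) for i, row in enumerate(csv.reader(fh)) if any(c.strip() for c in row)]
    if not raw_rows:
        raise ValueError(f"{path} is empty")

    def is_number(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    # drop a header row (first row with no numeric cell)
    first = raw_rows[0][1]
    if not any(is_number(c) for c in first):
        raw_rows = raw_rows[1:]
        if not raw_rows:
            raise ValueError(f"{path} has a header but no data rows")

    if all(len(row) == 1 for _, row in raw_rows):
        values = [_parse_cell(row[0].strip(), lineno, 1) for lineno, row in raw_rows]
        return [EcgSeries(values=np.array(values), id=path.stem)]

    series = []
    for lineno, row in raw_rows:
        cells = [c.strip() for c in row]
        sid, label = "", None
        col = 1
        if cells and not is_number(cells[0]):
            sid = cells[0]
            cells = cells[1:]
            col += 1
        if cells and not is_number(cells[0]):
            if cells[0] not in _LABELS:
                raise ValueError(
                    f"unknown label {cells[0]!r} at row {lineno} (expected one of {_LABELS})"
                )
            label = cells[0]
            cells = cells[1:]
            col += 1
        values = [_parse_cell(c, lineno, col + k) for k, c in enumerate(cells)]
        if not values:
            raise ValueError(f"row {lineno} has no numeric values")
        series.append(EcgSeries(values=np.array(values), label=label, id=sid or f"row{lineno}"))
    return series


def write_series_csv(path: str | Path, series_list: list[EcgSeries]) -> None:
    """One series per row: id, label, then the sample values."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for s in series_list:
            w.writerow([s.id, s.label or "unknown", *(f"{v:.6f}" for v in s.values)])


def write_single_series_csv(path: str | Path, values: np.ndarray, header: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([header])
        for v in np.asarray(values):
            w.writerow([f"{v:.6f}"])


def write_verdicts_tsv(path: str | Path, rows: list[dict]) -> None:
    """Per-series verdict table; column set taken from the first row."""
    if not rows:
        raise ValueError("no verdict rows to write")
    cols = list(rows[0])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for r in rows:
            w.writerow([r[c] for c in cols])


def write_decomposition_csv(path: str | Path, dec) -> None:
    """Columns t, original, trend_cycle, seasonal."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "original", "trend_cycle", "seasonal"])
        for t, (o, tr, se) in enumerate(zip(dec.original, dec.trend_cycle, dec.seasonal), start=1):
            w.writerow([t, f"{o:.6f}", f"{tr:.6f}", f"{se:.6f}"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_MODES = ("synth", "cycle", "patterns", "lflf")


@dataclass(frozen=True)
class RunConfig:
    """One JSON document describing a full pipeline run."""

    mode: str
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    policy: DiagnosisPolicy = field(default_factory=DiagnosisPolicy)
    lflf_settings: lflf.LflfConfig = field(default_factory=lflf.LflfConfig)
    n_healthy: int = 36
    n_sick: int = 34

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["lflf_settings"]["signature_menu"] = list(doc["lflf_settings"]["signature_menu"])
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        if not isinstance(doc, dict):
            raise ValueError("run config must be a JSON object")

        def build(dc_type, sub: dict, where: str):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")
            return dc_type(**sub)

        sub_builders = {
            "training": TrainingConfig,
            "policy": DiagnosisPolicy,
            "lflf_settings": lflf.LflfConfig,
        }
        kwargs = {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown key(s) {sorted(unknown)} in run config")
        for key, value in doc.items():
            if key in sub_builders:
                if key == "lflf_settings" and "signature_menu" in value:
                    value = dict(value, signature_menu=tuple(value["signature_menu"]))
                kwargs[key] = build(sub_builders[key], value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Pipeline dispatch
# ---------------------------------------------------------------------------


def _run_synth(config: RunConfig) -> None:
    out_dir = Path(config.paths.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = synth.CohortSpec(config.n_healthy, config.n_sick, rng_seed=config.seed)
    cohort = synth.generate_cohort(spec)
    write_series_csv(out_dir / "cohort.csv", cohort)
    healthy = [s for s in cohort if s.label == "healthy"][:10]
    sick = [s for s in cohort if s.label == "sick"][:10]
    if len(healthy) == 10:
        write_single_series_csv(out_dir / "HS.csv", synth.build_learning_series(healthy))
    if len(sick) == 10:
        write_single_series_csv(out_dir / "SS.csv", synth.build_learning_series(sick))
    logger.info("synth: wrote %d series to %s", len(cohort), out_dir)


def _run_cycle(config: RunConfig) -> None:
    training = dataclasses.replace(config.training, rng_seed=config.seed)
    cohort = read_series_csv(config.paths["train"])
    net, report = classifiers.train_cycle_classifier(cohort, training)
    logger.info("cycle net: converged=%s after %d epochs", report.converged, report.epochs_run)
    if "model_out" in config.paths:
        save_model(config.paths["model_out"], net, training)
    if "test" in config.paths:
        rows = []
        for s in read_series_csv(config.paths["test"]):
            d = classifiers.classify_cycle(s, net, config.policy)
            rows.append({"id": s.id, "verdict": d.verdict, "z": f"{d.evidence:.4f}"})
        write_verdicts_tsv(config.paths.get("verdicts_out", "verdicts.tsv"), rows)


def _run_patterns(config: RunConfig) -> None:
    training = dataclasses.replace(config.training, rng_seed=config.seed)
    net, report = classifiers.train_pattern_net(training)
    logger.info("pattern net: converged=%s after %d epochs", report.converged, report.epochs_run)
    if "model_out" in config.paths:
        save_model(config.paths["model_out"], net, training)
    if "test" in config.paths:
        rows = []
        for s in read_series_csv(config.paths["test"]):
            res = classifiers.recognize_patterns(s, net, config.policy)
            d = classifiers.diagnose_by_patterns(res, config.policy)
            rows.append(
                {
                    "id": s.id,
                    "verdict": d.verdict,
                    "p_S": f"{res.p_S:.4f}",
                    "p_H": f"{res.p_H:.4f}",
                }
            )
        write_verdicts_tsv(config.paths.get("verdicts_out", "verdicts.tsv"), rows)


def _run_lflf(config: RunConfig) -> None:
    healthy = read_series_csv(config.paths["healthy"])[0].values
    sick = read_series_csv(config.paths["sick"])[0].values
    rows = []
    for s in read_series_csv(config.paths["tested"]):
        result = lflf.classify_by_smape(healthy, sick, s.values, config.lflf_settings)
        rows.append(
            {
                "id": s.id,
                "verdict": result.verdict,
                "smape_healthy": f"{result.smape_healthy:.5f}",
                "smape_sick": f"{result.smape_sick:.5f}",
            }
        )
    write_verdicts_tsv(config.paths.get("verdicts_out", "verdicts.tsv"), rows)


def run_pipeline(config: RunConfig) -> int:
    """Dispatch one configured run; returns a process exit status."""
    logger.info("run: mode=%s seed=%d", config.mode, config.seed)
    try:
        {"synth": _run_synth, "cycle": _run_cycle, "patterns": _run_patterns, "lflf": _run_lflf}[
            config.mode
        ](config)
    except (ValueError, KeyError, OSError) as exc:
        logger.error("run failed: %s", exc)
        return 1
    return 0
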