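"""End-to-end benchmark orchestration: simulate -> filter -> netmats -> classify -> compare.

A benchmark evaluates a factorial grid of (dependency measure x temporal
filter) cells on one shared dataset with one shared LOSO fold plan, so that
McNemar pairing between cells is valid.  Each cell yields a CVResult; cells
are compared against a designated baseline cell with BH-FDR over the family.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import netmats as nm
from .discrimination import (ClassifierConfig, CVResult, FeatureTable, run_loso)
from .spectral import DRIFT_CUTOFF_HZ, FilterSpec, filter_series
from .statscompare import MultipleTestingConfig, compare_pipelines
from .synthdata import SimulationConfig, StudyDataset, read_dataset, simulate_dataset


@dataclass(frozen=True)
class MeasureSpec:
    """One dependency measure plus its lambda policy (partial correlation only).

    ``lambdas``: None for lambda-free measures; a single value for fixed
    ridge regularization; several values to activate nested selection.
    """

    measure: str
    lambdas: tuple[float, ...] | None = None
    fisher_z: bool = True

    @property
    def name(self) -> str:
        return self.measure


@dataclass(frozen=True)
class RunConfig:
    """Declarative benchmark configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_manifest: str | None = None
    measures: tuple[MeasureSpec, ...] = (
        MeasureSpec("correlation"),
        MeasureSpec("partial_correlation", lambdas=(0.1, 0.5, 1.0, 2.0)),
    )
    filters: tuple[tuple[str, FilterSpec | None], ...] = (("drift_only", None),)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    testing: MultipleTestingConfig = field(default_factory=MultipleTestingConfig)
    baseline: str | None = None  # cell name "measure|filter"; default first cell
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = SimulationConfig(**raw.get("simulation", {}))
        measures = tuple(
            MeasureSpec(m["measure"],
                        tuple(m["lambdas"]) if m.get("lambdas") else None,
                        m.get("fisher_z", True))
            for m in raw.get("measures", [{"measure": "correlation"}])
        )
        fs = sim.sampling_rate
        filters: list[tuple[str, FilterSpec | None]] = []
        for f in raw.get("filters", [{"name": "drift_only"}]):
            if f.get("kind") is None:
                filters.append((f.get("name", "drift_only"), None))
            else:
                spec = FilterSpec(f["kind"], tuple(f["cutoffs_hz"]),
                                  f.get("sampling_rate", fs), f.get("order", 4))
                filters.append((f.get("name", f["kind"]), spec))
        clf = ClassifierConfig(**raw.get("classifier", {}))
        testing = MultipleTestingConfig(**raw.get("testing", {}))
        return cls(simulation=sim, input_manifest=raw.get("input_manifest"),
                   measures=measures, filters=tuple(filters), classifier=clf,
                   testing=testing, baseline=raw.get("baseline"),
                   seed=int(raw.get("seed", sim.seed)))

    def config_hash(self) -> str:
        blob = json.dumps(_serializable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _serializable(obj) -> object:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _serializable(v) for k, v in obj.items()}
    return obj


def drift_highpass(sampling_rate: float) -> FilterSpec:
    """The 'no filtering' pipeline: removal of <0.005 Hz drift only."""
    return FilterSpec("highpass", (DRIFT_CUTOFF_HZ,), sampling_rate)


def apply_filter(dataset: StudyDataset, spec: FilterSpec | None) -> StudyDataset:
    """Filter every sample (None = drift-removal high-pass only)."""
    if spec is None:
        spec = drift_highpass(1.0 / dataset.sampling_interval)
    filtered = {k: filter_series(ts, spec) for k, ts in dataset.samples.items()}
    return StudyDataset(filtered, dataset.sampling_interval, dataset.provenance)


def feature_table(
    dataset: StudyDataset,
    measure: str,
    lam: float = 0.1,
    fisher_z: bool = True,
) -> FeatureTable:
    """Vectorized netmat features for every (subject, state) sample."""
    keys = sorted(dataset.samples)
    rows = [
        nm.vectorize_features(nm.compute_netmat(dataset.samples[k], measure, lam, fisher_z))
        for k in keys
    ]
    n_nodes = dataset.n_nodes
    names = tuple(nm.pair_labels(n_nodes)) if measure != "amplitude" else tuple(
        f"node_{i}" for i in range(n_nodes))
    return FeatureTable(
        np.asarray(rows),
        np.array([k[0] for k in keys]),
        np.array([k[1] for k in keys]),
        feature_names=names,
        provenance={"measure": measure, "lambda": lam if measure == "partial_correlation" else None},
    )


def feature_tables_by_lambda(
    dataset: StudyDataset, lambdas: Sequence[float], fisher_z: bool = True
) -> dict[float, FeatureTable]:
    """Ridge partial-correlation features recomputed at every lambda."""
    return {
        float(lam): feature_table(dataset, "partial_correlation", float(lam), fisher_z)
        for lam in lambdas
    }


@dataclass
class BenchmarkResult:
    """All per-cell CVResults plus the summary tables of one benchmark run."""

    cells: dict[str, CVResult]
    summary: pd.DataFrame
    comparison: pd.DataFrame
    config_hash: str
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
        for name, res in self.cells.items():
            safe = name.replace("|", "_")
            res.to_frame().to_csv(out / f"predictions_{safe}.tsv", sep="\t", index=False)
        meta = {"config_hash": self.config_hash, "seed": self.seed}
        (out / "run.json").write_text(json.dumps(meta, indent=2))


def run_benchmark(config: RunConfig) -> BenchmarkResult:
    """Run the full (measure x filter) factorial benchmark.

    All cells share the same dataset, sample set and LOSO fold plan, so the
    per-cell predictions are strictly paired; a cell failure is recorded and
    other cells proceed.
    """
    if config.input_manifest:
        dataset = read_dataset(config.input_manifest)
    else:
        from dataclasses import replace

        sim = replace(config.simulation, seed=config.seed)
        dataset, _ = simulate_dataset(sim)

    cells: dict[str, CVResult] = {}
    summary_rows = []
    errors: dict[str, str] = {}
    for filt_name, filt_spec in config.filters:
        filtered = apply_filter(dataset, filt_spec)
        for mspec in config.measures:
            name = f"{mspec.name}|{filt_name}"
            try:
                if mspec.measure == "partial_correlation" and mspec.lambdas and len(mspec.lambdas) > 1:
                    tables = feature_tables_by_lambda(filtered, mspec.lambdas, mspec.fisher_z)
                    res = run_loso(config=config.classifier, tables_by_lambda=tables)
                else:
                    lam = mspec.lambdas[0] if mspec.lambdas else 0.1
                    table = feature_table(filtered, mspec.measure, lam, mspec.fisher_z)
                    res = run_loso(table, config.classifier)
            except Exception as err:  # keep other cells alive
                errors[name] = f"{type(err).__name__}: {err}"
                continue
            cells[name] = res
            lam_summary = res.lambda_summary()
            summary_rows.append({
                "cell": name,
                "measure": mspec.name,
                "filter": filt_name,
                "accuracy_pct": res.accuracy,
                "lambda_mean": lam_summary["mean"],
                "lambda_min": lam_summary["min"],
                "lambda_max": lam_summary["max"],
            })

    summary = pd.DataFrame(summary_rows)
    baseline = config.baseline or (next(iter(cells)) if cells else None)
    if baseline is not None and baseline in cells and len(cells) > 1:
        comparison = compare_pipelines(cells, baseline, config.testing)
    else:
        comparison = pd.DataFrame()
    if errors:
        summary.attrs["errors"] = errors
    return BenchmarkResult(cells, summary, comparison, config.config_hash(), config.seed)


def hpf_sweep(
    dataset: StudyDataset,
    cutoffs_hz: Sequence[float],
    measure: str = "correlation",
    lam: float = 0.1,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Accuracy as a function of high-pass cutoff (accuracy-vs-HPF curve).

    Sweeps high-pass cutoffs (e.g. 0.005 to 0.375 Hz) for one measure and
    returns a tidy (cutoff_hz, accuracy_pct) table.
    """
    fs = 1.0 / dataset.sampling_interval
    rows = []
    for cutoff in cutoffs_hz:
        spec = FilterSpec("highpass", (float(cutoff),), fs)
        filtered = apply_filter(dataset, spec)
        table = feature_table(filtered, measure, lam)
        res = run_loso(table, classifier)
        rows.append({"cutoff_hz": float(cutoff), "accuracy_pct": res.accuracy})
    return pd.DataFrame(rows)
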