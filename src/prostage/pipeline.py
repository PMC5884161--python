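"""End-to-end orchestration: simulate/load -> encode -> train -> fuse -> report.

Every stage is seeded and the full configuration is captured into the output
directory, so a run is reproducible from its :class:`RunConfig` alone.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dbn, fusion
from .data import (
    CLINICAL_T_CATEGORIES,
    GLEASON_CATEGORIES,
    Label,
    PatientRecord,
    labeled_only,
    read_cohort,
    split_cohort,
    write_cohort,
)
from .encoding import encode_cohort
from .evaluation import EvalReport, EvalRow, evaluate_scores, roc_curve
from .synthetic import GeneratorConfig, default_tables, generate_cohort

log = logging.getLogger("prostage")

FEATURES = ("initial_psa", "gleason", "clinical_t")
#: display names matching the three per-feature classifiers
FEATURE_TITLES = {
    "initial_psa": "DBN#1 (initial PSA)",
    "gleason": "DBN#2 (Gleason score)",
    "clinical_t": "DBN#3 (clinical T stage)",
}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one input source: a cohort CSV path, or a synthetic generator
    size+seed.  Per-feature training configs default to the published
    schedule (100 unsupervised epochs per layer, 1000 backpropagation
    epochs); per-source discount rates default to 0 (sources fully trusted).
    """

    cohort_csv: str | None = None
    synthetic_n: int | None = 6345
    synthetic_seed: int = 0
    split_fraction: float = 0.7
    split_seed: int = 0
    training: dict[str, dbn.TrainingConfig] = field(
        default_factory=lambda: {f: dbn.TrainingConfig(seed=i) for i, f in enumerate(FEATURES)}
    )
    discounts: dict[str, float] = field(default_factory=lambda: {f: 0.0 for f in FEATURES})
    outdir: str = "prostage_out"

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.synthetic_n is None):
            raise ValueError("exactly one input source (cohort_csv xor synthetic_n) required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["training"] = {k: asdict(v) for k, v in self.training.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "training" in d:
            d["training"] = {k: dbn.TrainingConfig(**v) for k, v in d["training"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_input(config: RunConfig) -> list[PatientRecord]:
    if config.cohort_csv is not None:
        records, report = read_cohort(config.cohort_csv)
        if report.n_rejected:
            log.warning("rejected %d rows while loading %s", report.n_rejected, config.cohort_csv)
        return records
    gen = GeneratorConfig(n=config.synthetic_n, seed=config.synthetic_seed, tables=default_tables())
    return generate_cohort(gen)


def cmd_simulate(config: RunConfig, flag_threshold_points: float = 3.0) -> pd.DataFrame:
    """Generate a synthetic cohort CSV plus an empirical-vs-target report.

    The report lists, per class and category, the generator's target
    proportion and the empirical share in the drawn cohort, flagging any
    deviation above ``flag_threshold_points`` percentage points.
    """
    if config.synthetic_n is None:
        raise ValueError("simulate requires a synthetic input source")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = default_tables()
    cohort = generate_cohort(GeneratorConfig(config.synthetic_n, config.synthetic_seed, tables))
    write_cohort(cohort, outdir / "cohort.csv")

    rows = []
    for cls in (Label.OCD, Label.NOCD):
        members = [r for r in cohort if r.label == cls]
        n = max(len(members), 1)
        for cats, probs, getter in (
            (GLEASON_CATEGORIES, tables.gleason_probs(cls), lambda r: r.gleason),
            (CLINICAL_T_CATEGORIES, tables.clinical_t_probs(cls), lambda r: r.clinical_t),
        ):
            for cat, target in zip(cats, probs):
                emp = sum(1 for r in members if getter(r) == cat) / n
                rows.append(
                    {
                        "class": cls.value,
                        "category": cat,
                        "target_pct": 100 * target,
                        "empirical_pct": 100 * emp,
                        "flagged": abs(100 * (emp - target)) > flag_threshold_points,
                    }
                )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "generation_report.csv", index=False)
    config.save(outdir / "config.yaml")
    return report


def train_models(
    records: Sequence[PatientRecord],
    training: Mapping[str, dbn.TrainingConfig],
) -> dict[str, dbn.DBNClassifier]:
    """Train the three per-feature networks on a labelled record sequence."""
    records = labeled_only(records)
    if not records:
        raise ValueError("training requires labelled records")
    encoded = encode_cohort(records)
    labels = [r.label for r in records]
    models = {}
    for feature in FEATURES:
        t0 = time.perf_counter()
        models[feature] = dbn.train_dbn(
            encoded[feature], labels, training[feature], feature_name=feature
        )
        log.info("trained %s in %.1fs", feature, time.perf_counter() - t0)
    return models


def cmd_train(config: RunConfig) -> dict[str, dbn.DBNClassifier]:
    """Train on the configured source's training split; write model archives."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = labeled_only(_load_input(config))
    split = split_cohort(cohort, config.split_fraction, config.split_seed)
    models = train_models(split.train, config.training)
    for feature, model in models.items():
        dbn.save_classifier(model, outdir / f"model_{feature}.json")
    with open(outdir / "training_log.json", "w") as fh:
        json.dump(
            {f: {"finetune_loss": list(m.training_loss)} for f, m in models.items()}, fh
        )
    config.save(outdir / "config.yaml")
    return models


def predict_masses(
    models: Mapping[str, dbn.DBNClassifier],
    records: Sequence[PatientRecord],
    discounts: Mapping[str, float] | None = None,
) -> tuple[dict[str, list[fusion.MassFunction]], list[fusion.FusionResult]]:
    """Per-record mass functions for each source and the fused result."""
    discounts = discounts or {f: 0.0 for f in FEATURES}
    encoded = encode_cohort(records)
    masses: dict[str, list[fusion.MassFunction]] = {}
    for feature in FEATURES:
        probs = dbn.predict_proba(models[feature], encoded[feature])
        masses[feature] = [
            fusion.discount(fusion.mass_from_outputs(p[0], p[1]), discounts[feature])
            for p in np.atleast_2d(probs)
        ]
    fused = [
        fusion.combine_all([masses[f][i] for f in FEATURES]) for i in range(len(records))
    ]
    return masses, fused


def _combo_rows(
    split_name: str,
    records: Sequence[PatientRecord],
    masses: Mapping[str, list[fusion.MassFunction]],
) -> list[EvalRow]:
    """The seven classifier-combination rows for one split: each single
    source, each pair, and the full triple fusion."""
    labels = [r.label for r in records]
    rows = []
    combos = [
        c
        for k in (1, 2, 3)
        for c in itertools.combinations(FEATURES, k)
    ]
    for combo in combos:
        if len(combo) == 1:
            per_case = masses[combo[0]]
            scores = [m.m_nocd for m in per_case]
            decisions = [fusion.decide(m) for m in per_case]
        else:
            results = [
                fusion.combine_all([masses[f][i] for f in combo]) for i in range(len(records))
            ]
            scores = [res.combined.m_nocd for res in results]
            decisions = [res.decision for res in results]
        title = ", ".join(FEATURE_TITLES[f].split(" ")[0] for f in combo)
        if len(combo) == 3:
            title += " (proposed)"
        rows.append(evaluate_scores(title, split_name, labels, scores, decisions))
    return rows


def cmd_evaluate(
    config: RunConfig,
    models: Mapping[str, dbn.DBNClassifier] | None = None,
) -> EvalReport:
    """Evaluate singles, pairs and the triple fusion on both splits.

    Writes the metric table (CSV + text), per-classifier ROC point files and
    the full fusion trace for the validation split.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if models is None:
        models = {
            f: dbn.load_classifier(outdir / f"model_{f}.json") for f in FEATURES
        }
    cohort = labeled_only(_load_input(config))
    split = split_cohort(cohort, config.split_fraction, config.split_seed)

    rows: list[EvalRow] = []
    for split_name, records in (("training", split.train), ("validation", split.validation)):
        masses, fused = predict_masses(models, records, config.discounts)
        rows.extend(_combo_rows(split_name, records, masses))
        if split_name == "validation":
            _write_fusion_trace(outdir / "fusion_trace.csv", records, masses, fused)
            labels = [r.label for r in records]
            for feature in FEATURES:
                pts = roc_curve([m.m_nocd for m in masses[feature]], labels)
                _write_roc(outdir / f"roc_{feature}.csv", pts)
            pts = roc_curve([res.combined.m_nocd for res in fused], labels)
            _write_roc(outdir / "roc_fused.csv", pts)

    report = EvalReport(rows=tuple(rows))
    report.to_csv(outdir / "report.csv")
    (outdir / "report.txt").write_text(str(report) + "\n")

    _warn_if_fusion_trails(report)
    return report


def _warn_if_fusion_trails(report: EvalReport, margin: float = 0.01) -> None:
    """Soft check: fused validation accuracy should not trail any single
    source by more than a point (an observation, not a guarantee)."""
    val = {r.classifier: r for r in report.rows if r.split == "validation"}
    fused = next((r for r in val.values() if "proposed" in r.classifier), None)
    if fused is None:
        return
    for name, row in val.items():
        if "," not in name and "proposed" not in name and row.accuracy - fused.accuracy > margin:
            log.warning(
                "fused validation accuracy %.4f trails %s (%.4f) by more than %.2f",
                fused.accuracy, name, row.accuracy, margin,
            )


def _write_roc(path: Path, points) -> None:
    pd.DataFrame(
        {"threshold": p.threshold, "fpr": p.fpr, "tpr": p.tpr} for p in points
    ).to_csv(path, index=False)


def _write_fusion_trace(
    path: Path,
    records: Sequence[PatientRecord],
    masses: Mapping[str, list[fusion.MassFunction]],
    fused: Sequence[fusion.FusionResult],
) -> None:
    rows = []
    for i, (r, res) in enumerate(zip(records, fused)):
        row = {"id": r.record_id if r.record_id is not None else str(i)}
        for feature in FEATURES:
            m = masses[feature][i]
            row.update(
                {f"{feature}_m_ocd": m.m_ocd, f"{feature}_m_nocd": m.m_nocd, f"{feature}_m_theta": m.m_theta}
            )
        for step, p in enumerate(res.conflict_trace, start=1):
            row[f"conflict_step{step}"] = p
        row.update(
            {
                "m_ocd": res.combined.m_ocd,
                "m_nocd": res.combined.m_nocd,
                "m_theta": res.combined.m_theta,
                "bel_ocd": res.interval_ocd.bel,
                "pls_ocd": res.interval_ocd.pls,
                "bel_nocd": res.interval_nocd.bel,
                "pls_nocd": res.interval_nocd.pls,
                "decision": res.decision.value,
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cmd_predict(
    models: Mapping[str, dbn.DBNClassifier],
    records: Sequence[PatientRecord],
    out_csv: str | Path | None = None,
    discounts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-patient masses, evidential intervals and decisions as a table."""
    masses, fused = predict_masses(models, records, discounts)
    rows = []
    for i, (r, res) in enumerate(zip(records, fused)):
        rows.append(
            {
                "id": r.record_id if r.record_id is not None else str(i),
                **{
                    f"{f}_m_{k}": getattr(masses[f][i], f"m_{k}")
                    for f in FEATURES
                    for k in ("ocd", "nocd", "theta")
                },
                "m_ocd": res.combined.m_ocd,
                "m_nocd": res.combined.m_nocd,
                "m_theta": res.combined.m_theta,
                "bel_ocd": res.interval_ocd.bel,
                "pls_ocd": res.interval_ocd.pls,
                "bel_nocd": res.interval_nocd.bel,
                "pls_nocd": res.interval_nocd.pls,
                "decision": res.decision.value,
            }
        )
    frame = pd.DataFrame(rows)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame


def run_all(config: RunConfig) -> EvalReport:
    """simulate (if synthetic) -> train -> evaluate, all into config.outdir."""
    if config.synthetic_n is not None:
        cmd_simulate(config)
    models = cmd_train(config)
    return cmd_evaluate(config, models)
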