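"""Configuration-driven orchestration of the full simplification funnel.

Stages, in order: enumerate the combinatorial library; compute and clean
training descriptors; hybrid feature selection per target; grid-search SVR
training plus the validation panel; streamed library prediction with
extrapolation flags; top-set selection, substituent frequencies and
privileged lists; simplified-candidate generation and prediction; Pareto
ranking and the diversity-aware final pick.

Every stage reads its inputs from and writes its outputs to the run's
output directory, so stages can be re-run individually (the CLI exposes
one sub-command per stage) and a crashed run keeps its partial artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from simplihit import benchmark as bm
from simplihit import descriptors as de
from simplihit import enumeration as en
from simplihit import qsar
from simplihit import simplification as sim
from simplihit.feature_selection import FeatureSelectionResult, SelectionConfig, hybrid_select
from simplihit.pareto import diversity_pick, rank_candidates, round_report


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a run needs; serialisable to/from YAML.

    Exactly one input source: ``benchmark`` parameters (synthetic data) or
    explicit ``scaffold_smiles``/``scaffold_positions``/``substituents_csv``
    /``training_csv`` paths.  The training CSV needs a ``smiles`` column and
    one ``pIC50_<target>`` column per target.
    """

    outdir: str = "simplihit_run"
    seed: int = 0

    # --- input source -------------------------------------------------
    benchmark: dict[str, Any] | None = None
    n_train: int = 250
    scaffold_smiles: str | None = None
    scaffold_positions: list[str] | None = None
    substituents_csv: str | None = None
    training_csv: str | None = None

    # --- stage parameters ---------------------------------------------
    cfe_threshold: float = 0.3
    cv_folds: int = 5
    min_improvement: float = 1e-6
    grid: dict[str, list] | None = None
    y_rand_reps: int = 50
    top_n: int = 4000
    top_threshold: float = 7.0
    privileged_top_k: int | dict[str, int] = 2
    privileged_min_fraction: float | None = None
    max_decorations: int = 2
    anchor: str | None = None
    quota: int = 17
    count_only: bool = False
    chunk_size: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            cfe_threshold=self.cfe_threshold,
            cv_folds=self.cv_folds,
            cv_seed=self.seed,
            min_improvement=self.min_improvement,
        )


@dataclass
class RunReport:
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    validation: dict[str, dict] = field(default_factory=dict)
    selection_ids: list[str] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _log(msg: str) -> None:
    print(f"[simplihit] {msg}", flush=True)


# ---------------------------------------------------------------------------
# stage: inputs (scaffold, substituents, training table)
# ---------------------------------------------------------------------------

def stage_inputs(config: RunConfig) -> None:
    """Materialise scaffold, substituent libraries and the training table."""
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    if config.benchmark is not None:
        params = dict(config.benchmark)
        params.setdefault("seed", config.seed)
        bench = bm.make_benchmark(**params)
        bench.write(out)
        mols, table = bm.sample_training_set(bench, config.n_train, seed=config.seed + 1)
        table = table.copy()
        table["assignment"] = [m.assignment_string() for m in mols]
        table.to_csv(out / "training.csv", index=False)
        _log(f"benchmark inputs: library size {bench.library_size()}, "
             f"{len(table)} training molecules")
    else:
        if not (config.scaffold_smiles and config.scaffold_positions
                and config.substituents_csv and config.training_csv):
            raise PipelineError(
                "config must set either benchmark parameters or all of "
                "scaffold_smiles/scaffold_positions/substituents_csv/training_csv"
            )
        scaffold = en.parse_scaffold(config.scaffold_smiles, config.scaffold_positions)
        (out / "scaffold.json").write_text(json.dumps(
            {"core_smiles": scaffold.core_smiles, "positions": list(scaffold.positions)},
            indent=2,
        ))
        en.SubstituentSet.from_csv(config.substituents_csv).to_csv(out / "substituents.csv")
        pd.read_csv(config.training_csv).to_csv(out / "training.csv", index=False)


def _load_scaffold(out: Path) -> en.AttachmentScaffold:
    data = json.loads((out / "scaffold.json").read_text())
    return en.parse_scaffold(data["core_smiles"], data["positions"])


def _load_substituents(out: Path) -> en.SubstituentSet:
    return en.SubstituentSet.from_csv(out / "substituents.csv")


def _targets(training: pd.DataFrame) -> list[str]:
    targets = [c[len("pIC50_"):] for c in training.columns if c.startswith("pIC50_")]
    if not targets:
        raise PipelineError("training table has no pIC50_<target> columns")
    return targets


# ---------------------------------------------------------------------------
# stage: enumerate
# ---------------------------------------------------------------------------

def stage_enumerate(config: RunConfig) -> int:
    out = config.out
    scaffold = _load_scaffold(out)
    subs = _load_substituents(out)
    total = en.count_library(subs)
    if config.count_only:
        _log(f"library size (count only): {total}")
        (out / "library_count.json").write_text(json.dumps({"count": total}))
        return total
    log = en.RejectionLog()
    n = en.write_smi(out / "library.smi", en.enumerate_library(scaffold, subs, log=log))
    log.write_tsv(out / "enumeration_rejections.tsv")
    _log(f"enumerated {n} of {total} products "
         f"({len(log.rejected)} rejected)")
    return n


# ---------------------------------------------------------------------------
# stage: describe (training descriptors)
# ---------------------------------------------------------------------------

def stage_describe(config: RunConfig) -> de.DescriptorMatrix:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    matrix = de.compute_descriptors(
        list(training["smiles"]), ids=[str(i) for i in training["molecule_id"]]
    )
    cleaned, report = de.clean_descriptors(matrix)
    cleaned.to_csv(out / "train_descriptors.csv")
    (out / "train_descriptor_stats.json").write_text(json.dumps({
        "feature_names": cleaned.feature_names,
        "ranges": {k: list(v) for k, v in cleaned.ranges.items()},
        "medians": cleaned.medians,
        "dropped_constant": report.dropped_constant,
        "dropped_missing": report.dropped_missing,
    }, indent=2))
    _log(f"training descriptors: {cleaned.values.shape[1]} features kept, "
         f"{len(report.dropped_constant)} constant and "
         f"{len(report.dropped_missing)} mostly-missing dropped")
    return cleaned


def _load_training_stats(out: Path) -> de.DescriptorMatrix:
    """Rebuild a zero-row carrier matrix holding the frozen training stats."""
    stats = json.loads((out / "train_descriptor_stats.json").read_text())
    carrier = de.DescriptorMatrix(
        ids=[],
        feature_names=stats["feature_names"],
        values=np.empty((0, len(stats["feature_names"]))),
    )
    carrier.ranges = {k: tuple(v) for k, v in stats["ranges"].items()}
    carrier.medians = stats["medians"]
    return carrier


# ---------------------------------------------------------------------------
# stage: select features + train models
# ---------------------------------------------------------------------------

def stage_select_features(config: RunConfig) -> dict[str, FeatureSelectionResult]:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    X = de.DescriptorMatrix.from_csv(out / "train_descriptors.csv").to_frame()
    results = {}
    for target in _targets(training):
        y = training[f"pIC50_{target}"].to_numpy()
        result = hybrid_select(X, y, qsar.make_svr, config.selection_config())
        result.to_json(out / f"features_{target}.json")
        results[target] = result
        _log(f"{target}: {len(result.selected)} features selected "
             f"(CFE removed {len(result.removed_by_cfe)}, RFE removed "
             f"{len(result.removed_by_rfe)}, RFA re-added {len(result.readded_by_rfa)})")
    return results


def stage_train(config: RunConfig) -> dict[str, qsar.QSARModel]:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    X = de.DescriptorMatrix.from_csv(out / "train_descriptors.csv").to_frame()
    models = {}
    validation = {}
    for target in _targets(training):
        y = training[f"pIC50_{target}"].to_numpy()
        selected = FeatureSelectionResult.from_json(out / f"features_{target}.json").selected
        model = qsar.grid_search_train(
            X, y, target_name=target, features=selected,
            grid=config.grid, cv_seed=config.seed, cv_folds=config.cv_folds,
        )
        report = qsar.validate_model(
            model, X, y, y_rand_reps=config.y_rand_reps, seed=config.seed
        )
        model.save(out / f"model_{target}")
        models[target] = model
        validation[target] = dataclasses.asdict(report)
        _log(f"{target}: R2(self)={report.r2_self:.3f} Q2={report.q2_loo:.3f} "
             f"CV5={report.r2_cv5:.3f} CV10={report.r2_cv10:.3f} "
             f"y-rand={report.y_rand_mean:.3f} ({report.n_features} features)")
    (out / "validation.json").write_text(json.dumps(validation, indent=2))
    return models


def _load_models(out: Path, targets) -> dict[str, qsar.QSARModel]:
    return {t: qsar.QSARModel.load(out / f"model_{t}") for t in targets}


# ---------------------------------------------------------------------------
# stage: predict the full library (streamed)
# ---------------------------------------------------------------------------

def stage_predict(config: RunConfig) -> int:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    targets = _targets(training)
    models = _load_models(out, targets)
    stats = _load_training_stats(out)
    n = 0
    header = (
        ["molecule_id", "smiles", "assignment"]
        + [f"pred_{t}" for t in targets]
        + [f"extrapolated_{t}" for t in targets]
        + ["mean_pic50"]
    )
    with open(out / "predictions.csv", "w") as fh:
        fh.write(",".join(header) + "\n")
        chunk: list[en.LibraryMolecule] = []

        def flush(chunk):
            nonlocal n
            if not chunk:
                return
            matrix = de.compute_descriptors(
                [m.smiles for m in chunk], ids=[str(m.library_id) for m in chunk]
            )
            X = de.apply_training_stats(matrix, stats).to_frame()
            records = qsar.make_prediction_records(
                models, X, [str(m.library_id) for m in chunk]
            )
            for mol, rec in zip(chunk, records):
                row = [rec.molecule_id, mol.smiles, mol.assignment_string()]
                row += [f"{rec.predictions[t]:.6f}" for t in targets]
                row += [str(int(rec.extrapolated[t])) for t in targets]
                row += [f"{rec.mean_pic50:.6f}"]
                fh.write(",".join(row) + "\n")
            n += len(chunk)

        for mol in en.read_smi(out / "library.smi"):
            chunk.append(mol)
            if len(chunk) >= config.chunk_size:
                flush(chunk)
                chunk = []
        flush(chunk)
    _log(f"predicted {n} library molecules for targets {targets}")
    return n


def _read_predictions(out: Path, targets) -> tuple[list[qsar.PredictionRecord], dict[str, en.LibraryMolecule]]:
    df = pd.read_csv(out / "predictions.csv", dtype={"molecule_id": str})
    records = []
    by_id = {}
    for row in df.itertuples(index=False):
        rec = qsar.PredictionRecord(
            molecule_id=row.molecule_id,
            predictions={t: float(getattr(row, f"pred_{t}")) for t in targets},
            extrapolated={t: bool(getattr(row, f"extrapolated_{t}")) for t in targets},
        )
        records.append(rec)
        by_id[row.molecule_id] = en.LibraryMolecule(
            smiles=row.smiles,
            assignment=en.LibraryMolecule.parse_assignment(row.assignment),
            library_id=int(row.molecule_id),
        )
    return records, by_id


# ---------------------------------------------------------------------------
# stage: simplify (top set -> frequencies -> privileged -> candidates)
# ---------------------------------------------------------------------------

def stage_simplify(config: RunConfig) -> list[sim.SimplifiedCandidate]:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    targets = _targets(training)
    scaffold = _load_scaffold(out)
    subs = _load_substituents(out)
    records, by_id = _read_predictions(out, targets)

    top = sim.select_top_set(records, n=config.top_n, threshold=config.top_threshold)
    if len(top) < config.top_n:
        _log(f"only {len(top)} compounds exceed mean pIC50 > {config.top_threshold} "
             f"(requested {config.top_n})")
    top_mols = [by_id[r.molecule_id] for r in top]
    freq = sim.substituent_frequencies(
        top_mols, subs, threshold=config.top_threshold, n_requested=config.top_n
    )
    freq.write_tsv(out / "frequencies.tsv")

    if config.privileged_min_fraction is not None:
        privileged = sim.privileged_substituents(
            freq, min_fraction=config.privileged_min_fraction
        )
    else:
        privileged = sim.privileged_substituents(freq, top_k=config.privileged_top_k)
    (out / "privileged.json").write_text(json.dumps(privileged, indent=2))

    log = en.RejectionLog()
    candidates = sim.generate_simplified(
        scaffold, privileged,
        max_decorations=config.max_decorations, anchor=config.anchor, log=log,
    )
    log.write_tsv(out / "simplification_rejections.tsv")

    models = _load_models(out, targets)
    stats = _load_training_stats(out)
    matrix = de.compute_descriptors(
        [c.smiles for c in candidates], ids=[c.candidate_id for c in candidates]
    )
    X = de.apply_training_stats(matrix, stats).to_frame()
    recs = qsar.make_prediction_records(models, X, [c.candidate_id for c in candidates])
    for cand, rec in zip(candidates, recs):
        cand.predictions = rec.predictions
        cand.mean_pic50 = rec.mean_pic50
        cand.extrapolated = rec.extrapolated
        cand.complexity = sim.complexity_score(cand.smiles)
    sim.write_candidates_csv(out / "simplified.csv", candidates)
    _log(f"top set {len(top)} -> privileged "
         f"{ {p: len(v) for p, v in privileged.items()} } -> "
         f"{len(candidates)} simplified candidates")
    return candidates


# ---------------------------------------------------------------------------
# stage: rank (Pareto + library rank + diversity pick)
# ---------------------------------------------------------------------------

def _load_candidates(out: Path, targets) -> list[sim.SimplifiedCandidate]:
    df = pd.read_csv(out / "simplified.csv")
    candidates = []
    for row in df.itertuples(index=False):
        preds = dict(
            (kv.split("=")[0], float(kv.split("=")[1]))
            for kv in row.predictions.split(";")
        )
        occupied = tuple(
            tuple(kv.split("=", 1)) for kv in row.occupied_positions.split(";")
        )
        cand = sim.SimplifiedCandidate(smiles=row.smiles, occupied_positions=occupied)
        cand.predictions = preds
        cand.mean_pic50 = float(row.mean_pic50)
        cand.complexity = float(row.complexity)
        candidates.append(cand)
    return candidates


def _stream_library_means(out: Path):
    with open(out / "predictions.csv") as fh:
        header = fh.readline().rstrip("\n").split(",")
        idx = header.index("mean_pic50")
        for line in fh:
            yield float(line.rstrip("\n").split(",")[idx])


def stage_rank(config: RunConfig) -> list[sim.SimplifiedCandidate]:
    out = config.out
    training = pd.read_csv(out / "training.csv")
    targets = _targets(training)
    candidates = _load_candidates(out, targets)
    ranked = rank_candidates(candidates, _stream_library_means(out), targets=targets)
    sim.write_candidates_csv(out / "ranked.csv", ranked)
    selection = diversity_pick(ranked, config.quota)
    rows = []
    for c in selection:
        row = {"candidate_id": c.candidate_id, "smiles": c.smiles}
        for t in targets:
            row[t] = round_report(c.predictions[t], 2)
        row["Mean"] = round_report(c.mean_pic50, 2)
        row["ParetoValue"] = c.pareto_value
        row["RankCombinatorial"] = c.rank_combinatorial
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "selection.csv", index=False)
    _log(f"ranked {len(ranked)} candidates, selected {len(selection)} "
         f"(quota {config.quota})")
    return selection


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

STAGES = (
    ("inputs", stage_inputs),
    ("enumerate", stage_enumerate),
    ("describe", stage_describe),
    ("select-features", stage_select_features),
    ("train", stage_train),
    ("predict", stage_predict),
    ("simplify", stage_simplify),
    ("rank", stage_rank),
)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order and assemble the run report."""
    out = config.out
    report = RunReport(seed=config.seed)
    for name, fn in STAGES:
        try:
            result = fn(config)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        if name == "enumerate":
            report.stage_counts["library"] = int(result)
        elif name == "simplify":
            report.stage_counts["simplified"] = len(result)
        elif name == "rank":
            report.stage_counts["selection"] = len(result)
            report.selection_ids = [c.candidate_id for c in result]
        if config.count_only and name == "enumerate":
            break
    if (out / "validation.json").exists():
        report.validation = json.loads((out / "validation.json").read_text())
    if (out / "predictions.csv").exists():
        with open(out / "predictions.csv") as fh:
            report.stage_counts["predicted"] = sum(1 for _ in fh) - 1
    if (out / "frequencies.tsv").exists():
        # top-set size is recorded in any frequency row's denominator
        freq = pd.read_csv(out / "frequencies.tsv", sep="\t")
        if len(freq):
            report.stage_counts["top_set"] = int(
                freq[freq.position == freq.position.iloc[0]]["count"].sum()
            )
    report.manifest = sorted(p.name for p in out.iterdir() if p.is_file())
    report.save(out / "run_report.json")
    return report
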