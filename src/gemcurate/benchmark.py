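"""Full-pipeline benchmark harness.

Runs the complete screen/classify/metric pipeline either on a
user-supplied genome-scale model plus phenotype tables, or — with no
external files — on a generated fixture suite as a self-contained
smoke test with planted ground truth.  External data are never
downloaded by this package; the caller must supply the SBML model and
the phenotype/synthetic-lethal tables, and may supply expected
checksums which are then verified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .edits import batch_curate
from .fixtures import FixtureSpec, generate_fixture
from .model import MediumSpec, apply_medium, read_model
from .phenotypes import classify_records, compute_metrics, read_phenotype_table
from .screens import essential_genes, essential_reactions, find_sl_pairs

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark", "MissingInputError"]


class MissingInputError(FileNotFoundError):
    """A required external input is absent; the message says what to
    supply and where it comes from."""


@dataclass(frozen=True)
class RunConfig:
    model_path: str | None = None
    media_paths: tuple[str, ...] = ()
    phenotype_path: str | None = None
    db_path: str | None = None
    threshold_fraction: float = 0.01
    n_suppressions: int = 2
    max_additions: int = 2
    seed: int = 0
    curate: bool = False
    checksums: Mapping[str, str] = field(default_factory=dict)


@dataclass
class BenchmarkReport:
    per_medium: dict = field(default_factory=dict)
    metrics_before: object = None
    metrics_after: object = None
    fixtures_only: bool = False
    config_hash: str = ""
    seed: int = 0


def _hash_config(config: RunConfig) -> str:
    raw = json.dumps(
        {
            "model": config.model_path,
            "media": list(config.media_paths),
            "phenotypes": config.phenotype_path,
            "db": config.db_path,
            "threshold": config.threshold_fraction,
            "n": config.n_suppressions,
            "adds": config.max_additions,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(raw.encode()).hexdigest()[:12]


def _check_file(path: str | None, what: str, hint: str, checksums: Mapping[str, str]):
    if path is None or not Path(path).exists():
        raise MissingInputError(
            f"missing {what}: {path!r}. {hint} This package never downloads "
            "external data; supply the file and re-run."
        )
    if path in checksums:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        if digest != checksums[path]:
            raise ValueError(
                f"checksum mismatch for {path}: expected {checksums[path]}, got {digest}"
            )


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Screens, classification and metrics, before and (optionally)
    after curation.

    Without a model path the harness runs in fixtures-only mode: a
    seeded synthetic fixture with planted mismatches is generated, the
    pipeline runs on it, and the report carries the planted-truth
    comparison — a full smoke test with no external files.
    """
    report = BenchmarkReport(config_hash=_hash_config(config), seed=config.seed)
    if config.model_path is None:
        return _fixtures_only(config, report)

    _check_file(
        config.model_path,
        "SBML model",
        "Supply a genome-scale model in SBML/fbc form (e.g. a BiGG export).",
        config.checksums,
    )
    _check_file(
        config.phenotype_path,
        "phenotype table",
        "Supply a TSV of experimental growth calls "
        "(columns: gene1, gene2, medium, phenotype, cause, supplement).",
        config.checksums,
    )
    model = read_model(config.model_path)
    calls = read_phenotype_table(config.phenotype_path)
    media = [MediumSpec.from_file(p) for p in config.media_paths] or [
        MediumSpec(name="minimal")
    ]
    all_records = []
    for medium in media:
        constrained = apply_medium(model, medium)
        calls_m = [c for c in calls if not c.medium or c.medium == medium.name]
        screen = essential_genes(constrained, medium.name, config.threshold_fraction)
        rxn_screen = essential_reactions(constrained, medium.name, config.threshold_fraction)
        sl = (
            find_sl_pairs(constrained, medium.name, config.threshold_fraction,
                          single_screen=screen)
            if any(len(c.genes) == 2 for c in calls_m)
            else None
        )
        records, skipped = classify_records(calls_m, screen, sl, model_genes=model.genes)
        report.per_medium[medium.name] = {
            "essential_genes": len(screen.essential_genes),
            "essential_reactions": len(rxn_screen.essential_reactions),
            "sl_pairs": len(sl.pairs) if sl is not None else None,
            "records": len(records),
            "skipped_calls": len(skipped),
            "metrics": compute_metrics(records),
        }
        all_records.extend(records)
    report.metrics_before = compute_metrics(all_records)
    if config.curate:
        ledger = batch_curate(
            model, calls, media,
            n_suppressions=config.n_suppressions,
            max_additions=config.max_additions,
            threshold_fraction=config.threshold_fraction,
        )
        report.metrics_after = ledger.metrics_after
    return report


def _fixtures_only(config: RunConfig, report: BenchmarkReport) -> BenchmarkReport:
    report.fixtures_only = True
    fx = generate_fixture(FixtureSpec(seed=config.seed))
    constrained = apply_medium(fx.model, fx.medium)
    screen = essential_genes(constrained, fx.medium.name, config.threshold_fraction)
    rxn_screen = essential_reactions(constrained, fx.medium.name, config.threshold_fraction)
    sl = find_sl_pairs(constrained, fx.medium.name, config.threshold_fraction,
                       single_screen=screen)
    records, _ = classify_records(fx.calls, screen, sl, model_genes=fx.model.genes)
    report.per_medium[fx.medium.name] = {
        "essential_genes": len(screen.essential_genes),
        "essential_reactions": len(rxn_screen.essential_reactions),
        "sl_pairs": len(sl.pairs),
        "records": len(records),
        "skipped_calls": 0,
        "metrics": compute_metrics(records),
        "planted_truth_recovered": (
            screen.essential_genes == frozenset(fx.ground_truth["essential_genes"])
            and sl.pairs == frozenset(fx.ground_truth["sl_pairs"])
        ),
    }
    report.metrics_before = compute_metrics(records)
    if config.curate:
        ledger = batch_curate(
            fx.model, fx.calls, [fx.medium],
            db_reactions=fx.db_reactions,
            n_suppressions=config.n_suppressions,
            max_additions=config.max_additions,
            threshold_fraction=config.threshold_fraction,
        )
        report.metrics_after = ledger.metrics_after
    return report
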