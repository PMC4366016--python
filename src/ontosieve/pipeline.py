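"""End-to-end orchestration: case assessment -> gain -> MI -> variants ->
index -> annotation -> evaluation.

The four experimental arms (baseline, case sensitivity only, information
gain only, both) differ solely in the ``case_mode`` / ``use_ig`` switches of
:class:`RunConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import __version__
from .case_sensitivity import CaseReport, assess_profiles
from .dfr_gain import compute_gain_table
from .evaluation import EvalResult, compare, load_gold
from .index_retrieval import Annotation, ConceptTokenIndex, annotate, build_index
from .lexicon_io import build_profiles, load_lexicon
from .mutual_info import compute_mi_stats
from .variant_generation import VariantParams, VariantSet, generate_variants

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_arms", "ARMS"]

ARMS = ("baseline", "cs", "ig", "cs+ig")


@dataclass(frozen=True)
class RunConfig:
    lexicon: str
    case_mode: str = "auto"  # auto | on | off
    use_ig: bool = False
    m: float = 1.0
    n: float = 0.0
    k: float = 3.0
    log_base: float = 2.0
    out_dir: str | None = None
    seed: int = 0
    documents: tuple[str, ...] = ()
    gold: str | None = None

    def __post_init__(self):
        if self.case_mode not in ("auto", "on", "off"):
            raise ValueError(f"invalid case_mode {self.case_mode!r}")


@dataclass
class PipelineResult:
    case_report: CaseReport
    case_sensitive: bool
    index: ConceptTokenIndex
    variants: VariantSet
    annotations: list[Annotation] = field(default_factory=list)
    evaluation: EvalResult | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute one arm of the pipeline; optionally persist artifacts.

    ``case_mode="auto"`` delegates to the CSS classification with its -1
    threshold.  With ``use_ig`` the gain/MI/variant stages run and the
    generated labels join the index.
    """
    concepts = load_lexicon(config.lexicon)
    probe_profiles, _ = build_profiles(concepts, case_sensitive_mode=False)
    case_report = assess_profiles(probe_profiles)
    if config.case_mode == "auto":
        case_sensitive = case_report.is_case_sensitive
    else:
        case_sensitive = config.case_mode == "on"

    profiles, stats = build_profiles(concepts, case_sensitive_mode=case_sensitive)

    variants = VariantSet()
    if config.use_ig:
        gain_table = compute_gain_table(profiles, stats, log_base=config.log_base)
        mi_stats = compute_mi_stats(profiles, m=config.m, n=config.n)
        params = VariantParams(m=config.m, n=config.n, k=config.k)
        variants = generate_variants(profiles, gain_table, mi_stats, params)

    index = build_index(
        profiles,
        variants,
        case_sensitive=case_sensitive,
        metadata={
            "lexicon": str(config.lexicon),
            "css": case_report.css,
            "case_mode": config.case_mode,
            "use_ig": config.use_ig,
            "m": config.m,
            "n": config.n,
            "k": config.k,
            "seed": config.seed,
            "version": __version__,
        },
    )

    annotations: list[Annotation] = []
    for doc_path in config.documents:
        doc_path = Path(doc_path)
        text = doc_path.read_text(encoding="utf-8")
        annotations.extend(annotate(doc_path.stem, text, index))

    evaluation = None
    if config.gold is not None:
        evaluation = compare(annotations, load_gold(config.gold))

    result = PipelineResult(
        case_report=case_report,
        case_sensitive=case_sensitive,
        index=index,
        variants=variants,
        annotations=annotations,
        evaluation=evaluation,
    )
    if config.out_dir is not None:
        _persist(config, result)
    return result


def _persist(config: RunConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.index.save(out / "index.json")
    with open(out / "variants.tsv", "w", encoding="utf-8") as fh:
        for rec in result.variants:
            fh.write(
                f"{rec.concept_id}\t{' '.join(rec.source_tokens)}\t"
                f"{' '.join(rec.variant_tokens)}\t{rec.rule.value}\n"
            )
    if result.annotations:
        with open(out / "annotations.tsv", "w", encoding="utf-8") as fh:
            for a in result.annotations:
                fh.write(f"{a.doc_id}\t{a.start}\t{a.end}\t{a.concept_id}\n")
    provenance = {
        "config": {
            "lexicon": str(config.lexicon),
            "case_mode": config.case_mode,
            "use_ig": config.use_ig,
            "m": config.m,
            "n": config.n,
            "k": config.k,
            "log_base": config.log_base,
            "seed": config.seed,
        },
        "version": __version__,
        "case_sensitive": result.case_sensitive,
        "css": result.case_report.css,
        "n_rows": len(result.index.rows),
        "n_variants": len(result.variants),
    }
    if result.evaluation is not None:
        provenance["evaluation"] = {
            "tp": result.evaluation.tp,
            "fp": result.evaluation.fp,
            "fn": result.evaluation.fn,
            "precision": result.evaluation.precision,
            "recall": result.evaluation.recall,
            "f1": result.evaluation.f1,
        }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))


def run_arms(config: RunConfig) -> dict[str, PipelineResult]:
    """Run all four experimental arms off one base configuration."""
    settings = {
        "baseline": dict(case_mode="off", use_ig=False),
        "cs": dict(case_mode="auto", use_ig=False),
        "ig": dict(case_mode="off", use_ig=True),
        "cs+ig": dict(case_mode="auto", use_ig=True),
    }
    results = {}
    for arm in ARMS:
        arm_out = None
        if config.out_dir is not None:
            arm_out = str(Path(config.out_dir) / arm.replace("+", "_"))
        results[arm] = run_pipeline(
            replace(config, out_dir=arm_out, **settings[arm])
        )
    return results
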