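"""End-to-end orchestration: a directory of patient VCFs in, tables out.

For each patient VCF the stages run: annotate variants on transcripts ->
extract mutant contexts -> enumerate epitopes -> predict MHC-I binding
(mutant and, when recognition is enabled, wild-type) -> classify binders ->
novelty vs reference proteome -> recognition potential -> clonality ->
write the SNV table, indel-type table, and burden summary. Failures are
isolated per patient: one bad VCF does not abort the batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .errors import ConfigError, NeoepitopeError
from .models import (
    BindingScore,
    BurdenSummary,
    EpitopeCandidate,
    EpitopeDatabase,
    ExpressionTable,
    HlaGenotype,
)
from . import binding, coding_change, epitope_enum, heterogeneity, io_formats
from . import recognition as recog
from .binding import HashPredictor, TablePredictor, load_netmhcpan_dir
from .recognition import RecognitionParams

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; mirrors the CLI flags and YAML keys."""

    vcf_dir: PathLike
    genome: PathLike
    transcripts: PathLike
    out_dir: PathLike
    hla: Optional[PathLike] = None
    hla_dialect: str = "simple_tsv"
    lengths: tuple[int, ...] = (8, 9, 10)
    sb_threshold: float = 0.5
    wb_threshold: float = 2.0
    filtered: bool = True
    predictor: str = "hash"  # hash | table | netmhcpan
    predictor_table: Optional[PathLike] = None
    netmhcpan_dir: Optional[PathLike] = None
    recognition: bool = False
    recognition_params: RecognitionParams = field(
        default_factory=RecognitionParams
    )
    epitope_db: Optional[PathLike] = None
    novelty: bool = False
    proteome: Optional[PathLike] = None
    expression: Optional[PathLike] = None
    hla_defaults: Optional[tuple[str, ...]] = None
    seed: int = 0
    counting_unit: str = "peptide_allele"


@dataclass
class PipelineResult:
    outputs: dict[str, dict[str, Path]]
    summaries: list[BurdenSummary]
    candidates: list[EpitopeCandidate]
    stage_counts: dict[str, dict[str, int]]
    warnings: list[str]
    status: int = 0


def validate_config(config: PipelineConfig) -> tuple[PipelineConfig, list[str]]:
    """Check paths and invariants; all violations are reported together."""
    errors: list[str] = []
    for name in ("vcf_dir", "genome", "transcripts"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            errors.append(f"{name}: path does not exist: {p}")
    if not (0 < config.sb_threshold <= config.wb_threshold):
        errors.append(
            "thresholds: require 0 < sb_threshold <= wb_threshold "
            f"(got {config.sb_threshold}, {config.wb_threshold})"
        )
    if not config.lengths:
        errors.append("lengths: at least one epitope length required")
    elif any(L < 8 or L > 14 for L in config.lengths):
        errors.append(f"lengths: must lie in [8, 14], got {config.lengths}")
    if config.hla_dialect not in ("simple_tsv", "polysolver_winners"):
        errors.append(f"hla_dialect: unknown dialect {config.hla_dialect!r}")
    if config.predictor == "table":
        if config.predictor_table is None or not Path(
            config.predictor_table
        ).exists():
            errors.append(
                f"predictor_table: required for the table predictor: "
                f"{config.predictor_table}"
            )
    elif config.predictor == "netmhcpan":
        if config.netmhcpan_dir is None or not Path(
            config.netmhcpan_dir
        ).is_dir():
            errors.append(
                f"netmhcpan_dir: required for the adapter predictor: "
                f"{config.netmhcpan_dir}"
            )
    elif config.predictor != "hash":
        errors.append(f"predictor: unknown predictor {config.predictor!r}")
    if config.novelty and (
        config.proteome is None or not Path(config.proteome).exists()
    ):
        errors.append(
            f"proteome: required when novelty filtering is on: "
            f"{config.proteome}"
        )
    if config.recognition and (
        config.epitope_db is None or not Path(config.epitope_db).exists()
    ):
        errors.append(
            f"epitope_db: required when recognition scoring is on: "
            f"{config.epitope_db}"
        )
    if config.counting_unit not in ("peptide_allele", "variant"):
        errors.append(f"counting_unit: unknown unit {config.counting_unit!r}")
    return config, errors


def _make_predictor(config: PipelineConfig):
    if config.predictor == "table":
        return TablePredictor.from_tsv(config.predictor_table)
    if config.predictor == "netmhcpan":
        return load_netmhcpan_dir(config.netmhcpan_dir)
    return HashPredictor(config.seed)


def _patient_hla(config: PipelineConfig, patient_id: str,
                 warnings: list[str]) -> HlaGenotype:
    if config.hla is None:
        return io_formats.default_hla(config.hla_defaults, patient_id)
    try:
        return io_formats.read_hla(
            config.hla, config.hla_dialect, patient_id
        )
    except NeoepitopeError as e:
        warnings.append(
            f"{patient_id}: HLA lookup failed ({e}); using default alleles"
        )
        return io_formats.default_hla(config.hla_defaults, patient_id)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow over every patient VCF in ``vcf_dir``."""
    config, errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))

    genome = {g.name: g for g in io_formats.read_fasta(config.genome)}
    transcripts = io_formats.read_transcripts(config.transcripts)
    predictor = _make_predictor(config)
    proteome = (
        [r.sequence for r in io_formats.read_protein_fasta(config.proteome)]
        if config.novelty
        else []
    )
    epitope_db = (
        io_formats.read_epitope_db(config.epitope_db)
        if config.recognition
        else EpitopeDatabase(())
    )
    expression = (
        io_formats.read_expression(config.expression)
        if config.expression
        else None
    )

    vcf_dir = Path(config.vcf_dir)
    vcfs = sorted(
        list(vcf_dir.glob("*.vcf")) + list(vcf_dir.glob("*.vcf.gz"))
    )
    if not vcfs:
        raise ConfigError(f"no VCF files found in {vcf_dir}")

    warnings: list[str] = []
    all_candidates: list[EpitopeCandidate] = []
    summaries: list[BurdenSummary] = []
    stage_counts: dict[str, dict[str, int]] = {}
    for vcf_path in vcfs:
        patient_id = vcf_path.name[: -len(".vcf.gz")] if vcf_path.name.endswith(
            ".vcf.gz"
        ) else vcf_path.stem
        try:
            cands, counts = _process_patient(
                vcf_path, patient_id, config, genome, transcripts,
                predictor, proteome, epitope_db, expression, warnings,
            )
        except NeoepitopeError as e:
            warnings.append(f"{patient_id}: skipped ({e})")
            log.warning("patient %s skipped: %s", patient_id, e)
            continue
        stage_counts[patient_id] = counts
        all_candidates.extend(cands)
        summaries.append(
            heterogeneity.summarize_burden(
                cands, patient_id, config.counting_unit
            )
        )
        log.info("patient %s: %s", patient_id, counts)

    outputs = io_formats.write_output_tables(
        all_candidates, summaries, config.out_dir
    )
    _write_manifest(config, vcfs, Path(config.out_dir))
    return PipelineResult(
        outputs=outputs,
        summaries=summaries,
        candidates=all_candidates,
        stage_counts=stage_counts,
        warnings=warnings,
        status=0,
    )


def _process_patient(
    vcf_path: Path,
    patient_id: str,
    config: PipelineConfig,
    genome,
    transcripts,
    predictor,
    proteome,
    epitope_db: EpitopeDatabase,
    expression: Optional[ExpressionTable],
    warnings: list[str],
) -> tuple[list[EpitopeCandidate], dict[str, int]]:
    variants = io_formats.read_vcf(vcf_path, patient_id)
    hla = _patient_hla(config, patient_id, warnings)
    max_len = max(config.lengths)

    counts = {
        "variants": len(variants),
        "coding_changes": 0,
        "contexts": 0,
        "enumerated_pairs": 0,
        "predictor_failures": 0,
        "nb_filtered": 0,
        "written": 0,
    }
    pairs = []
    for variant in variants:
        changes = coding_change.annotate_variant(
            variant, transcripts, genome, max_len
        )
        for change in changes:
            if change.change_class not in ("noncoding", "synonymous",
                                           "stop_gain"):
                counts["coding_changes"] += 1
            if change.mt_context is not None:
                counts["contexts"] += 1
                pairs.extend(
                    epitope_enum.enumerate_epitopes(change, config.lengths)
                )
    pairs = epitope_enum.dedupe_candidates(pairs)
    counts["enumerated_pairs"] = len(pairs)

    novelty_cache: dict[str, bool] = {}
    similarity_cache: dict[str, tuple[float, Optional[str]]] = {}
    candidates: list[EpitopeCandidate] = []
    for pair in pairs:
        for allele in hla.alleles:
            try:
                mt_score = predictor.score(pair.mt_peptide, allele)
            except NeoepitopeError as e:
                counts["predictor_failures"] += 1
                warnings.append(
                    f"{patient_id}: cannot score ({pair.mt_peptide}, "
                    f"{allele}): {e}"
                )
                continue
            binder_class = binding.classify_binder(
                mt_score.rank, config.sb_threshold, config.wb_threshold
            )
            if config.filtered and binder_class == "NB":
                counts["nb_filtered"] += 1
                continue
            cand = EpitopeCandidate(
                pair=pair,
                allele=allele,
                rank_mt=mt_score.rank,
                affinity_mt=mt_score.affinity,
                binder_class=binder_class,
            )
            if config.novelty:
                if pair.mt_peptide not in novelty_cache:
                    novelty_cache[pair.mt_peptide] = recog.is_novel(
                        pair.mt_peptide, proteome
                    )
                cand.novel = novelty_cache[pair.mt_peptide]
            if expression is not None:
                cand.expression = expression.value(
                    pair.change.transcript.gene_name
                )
            if config.recognition:
                # In filtered mode recognition is scored only for peptides
                # that passed the novelty screen; unfiltered scores all.
                skip = config.filtered and cand.novel is False
                if not skip:
                    _score_recognition(
                        cand, pair, allele, predictor, epitope_db,
                        config, similarity_cache, counts, warnings,
                    )
            candidates.append(cand)
    counts["written"] = len(candidates)
    return candidates, counts


def _score_recognition(
    cand, pair, allele, predictor, epitope_db, config,
    similarity_cache, counts, warnings,
):
    if pair.mt_peptide not in similarity_cache:
        similarity_cache[pair.mt_peptide] = recog.compute_R(
            pair.mt_peptide, epitope_db, config.recognition_params
        )
    R, best_id = similarity_cache[pair.mt_peptide]
    if pair.wt_peptide is not None:
        try:
            wt_score = predictor.score(pair.wt_peptide, allele)
        except NeoepitopeError as e:
            counts["predictor_failures"] += 1
            warnings.append(
                f"{cand.variant.patient_id}: cannot score WT "
                f"({pair.wt_peptide}, {allele}): {e}"
            )
            wt_score = None
        if wt_score is not None:
            cand.rank_wt = wt_score.rank
            cand.affinity_wt = wt_score.affinity
            mt_score = BindingScore(
                pair.mt_peptide, allele, cand.rank_mt, cand.affinity_mt
            )
            try:
                cand.amplitude = recog.compute_A(wt_score, mt_score)
            except ValueError:
                cand.amplitude = 1.0
                cand.amplitude_undefined = True
        else:
            cand.amplitude = 1.0
            cand.amplitude_undefined = True
    else:
        # Indel-type candidates lack a wild-type partner; report A := 1
        # with the amplitude_undefined flag rather than dropping them.
        cand.amplitude = 1.0
        cand.amplitude_undefined = True
    cand.similarity = R
    cand.best_epitope_id = best_id
    cand.potential = recog.recognition_potential(cand.amplitude, R)


def _write_manifest(config: PipelineConfig, vcfs: list[Path], out_dir: Path):
    """Reproducibility manifest: inputs, config hash, package version.

    ``out_dir`` is excluded from the hashed view so the same analysis
    written to two directories yields identical manifests.
    """
    cfg = asdict(config)
    cfg.pop("out_dir")
    cfg["recognition_params"] = asdict(config.recognition_params)
    view = {k: (str(v) if isinstance(v, Path) else v)
            for k, v in sorted(cfg.items())}
    digest = hashlib.sha256(
        json.dumps(view, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "package": "neoepitope",
        "version": __version__,
        "config": view,
        "config_sha256": digest,
        "inputs": [v.name for v in vcfs],
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
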