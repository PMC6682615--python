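"""End-to-end orchestration: ingest -> pairs -> distances -> association.

Each stage reads and writes plain-text tables so stages are independently
runnable and testable; the composite runner executes every stage for which
inputs exist and emits a JSON report with per-modality association
results and a provenance block (config hash, package version, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import MODALITIES, assemble_records, associate
from .cnv import build_event_matrix, cnv_pair_distances, read_cns, union_breakpoints
from .cohort import PairingConfig, enumerate_pairs, pairs_to_frame, read_coordinates
from .methylation import methylation_pair_distances, qc_filter, read_beta_matrix
from .mutations import (
    HypermutationConfig,
    MutationFilterConfig,
    build_af_matrix,
    filter_variants,
    flag_hypermutation,
    mutation_pair_distances,
    read_variant_table,
    write_variant_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for a composite pipeline run."""

    coordinates: str
    variants: str | None = None
    cnv_dir: str | None = None
    beta: str | None = None
    sample_meta: str | None = None
    outdir: str = "gliodist_out"
    seed: int = 0

    shallow_deep_mm: float = 5.0
    same_site_forceps_mm: float = 0.0
    exclude_same_site_forceps: bool = False

    filter: MutationFilterConfig = field(default_factory=MutationFilterConfig)
    exclude_hypermutated: bool = False
    hypermutation: HypermutationConfig = field(default_factory=HypermutationConfig)

    impute_neutral: bool = False
    drop_sex_chroms: bool = False

    k_probes: int = 500
    max_sample_missing_frac: float = 0.10
    max_probe_missing: int = 3

    permutation: bool = False
    n_perm: int = 1000

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "filter" in raw:
            raw["filter"] = MutationFilterConfig(**raw["filter"])
        if "hypermutation" in raw:
            raw["hypermutation"] = HypermutationConfig(**raw["hypermutation"])
        return cls(**raw)


def _config_hash(cfg: RunConfig) -> str:
    payload = asdict(cfg)
    payload.pop("outdir", None)  # analytic config only
    text = json.dumps(payload, sort_keys=True, default=sorted)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def mutation_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    calls = read_variant_table(cfg.variants)
    kept, tally = filter_variants(calls, cfg.filter, return_tally=True)
    write_variant_table(kept, outdir / "filtered_variants.tsv")

    counts: dict[str, int] = {}
    for c in kept:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    hyper = flag_hypermutation(counts, cfg.hypermutation) if counts else None
    if hyper and hyper.flagged_samples:
        logger.warning("hypermutation flags: %s", hyper.flagged_samples)
        if cfg.exclude_hypermutated:
            kept = [c for c in kept if not hyper.flags.get(c.sample_id, False)]

    tables = []
    by_patient: dict[str, list] = {}
    for c in kept:
        by_patient.setdefault(c.patient_id, []).append(c)
    for patient_id in sorted(by_patient):
        tables.append(mutation_pair_distances(build_af_matrix(by_patient[patient_id])))
    dist = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["patient_id", "sample_a", "sample_b", "jaccard_distance",
                     "n_union_mutations", "n_shared", "count_distance"]
        )
    )
    _write_tsv(dist, outdir / "mutation_distances.tsv")
    report = {
        "n_calls": len(calls),
        "n_retained": len(kept),
        "rejections": dict(tally),
        "hypermutation_flags": hyper.flagged_samples if hyper else [],
        "hypermutation_reference_count": hyper.reference_count if hyper else None,
    }
    (outdir / "mutation_stage.json").write_text(json.dumps(report, indent=1))
    return dist


def cnv_stage(cfg: RunConfig, outdir: Path, sample_to_patient: dict[str, str]) -> pd.DataFrame:
    cnv_dir = Path(cfg.cnv_dir)
    segments = []
    for path in sorted(cnv_dir.glob("*.cns")):
        sample_id = path.stem
        patient_id = sample_to_patient.get(sample_id)
        if patient_id is None:
            logger.warning("cnv: sample %s not in coordinates table; skipped", sample_id)
            continue
        segments.extend(read_cns(path, sample_id, patient_id))
    tables = []
    by_patient: dict[str, list] = {}
    for seg in segments:
        by_patient.setdefault(seg.patient_id, []).append(seg)
    for patient_id in sorted(by_patient):
        segs = by_patient[patient_id]
        events = union_breakpoints(segs)
        matrix = build_event_matrix(events, segs)
        matrix.to_frame().to_csv(
            outdir / f"cnv_events_{patient_id}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        tables.append(
            cnv_pair_distances(matrix, cfg.impute_neutral, cfg.drop_sex_chroms)
        )
    dist = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["patient_id", "sample_a", "sample_b", "canberra_distance", "n_events_shared"]
        )
    )
    _write_tsv(dist, outdir / "cnv_distances.tsv")
    return dist


def methylation_stage(cfg: RunConfig, outdir: Path) -> pd.DataFrame:
    matrix = read_beta_matrix(cfg.beta, cfg.sample_meta)
    matrix, qc_report = qc_filter(
        matrix, cfg.max_sample_missing_frac, cfg.max_probe_missing
    )
    (outdir / "methylation_qc.json").write_text(json.dumps(qc_report, indent=1))
    dist = methylation_pair_distances(matrix, k=cfg.k_probes)
    _write_tsv(dist, outdir / "methylation_distances.tsv")
    return dist


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages for which inputs exist and write the run report.

    Raises if no molecular input is configured. Modalities with fewer than
    3 joined pairs yield a null association flagged ``insufficient_n``.
    """
    if not any((cfg.variants, cfg.cnv_dir, cfg.beta)):
        raise ValueError("no molecular inputs configured (variants, cnv_dir or beta)")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites = read_coordinates(cfg.coordinates)
    pairing = PairingConfig(
        cfg.shallow_deep_mm, cfg.same_site_forceps_mm, cfg.exclude_same_site_forceps
    )
    pairs = enumerate_pairs(sites, pairing)
    pairs_df = pairs_to_frame(pairs)
    _write_tsv(pairs_df, outdir / "pairs.tsv")
    sample_to_patient = {s.sample_id: s.patient_id for s in sites}

    modality_tables: dict[str, pd.DataFrame] = {}
    if cfg.variants:
        modality_tables["mutation"] = mutation_stage(cfg, outdir)
    if cfg.cnv_dir:
        modality_tables["cnv"] = cnv_stage(cfg, outdir, sample_to_patient)
    if cfg.beta:
        if not cfg.sample_meta:
            raise ValueError("beta input requires sample_meta")
        modality_tables["methylation"] = methylation_stage(cfg, outdir)

    records = assemble_records(pairs_df, modality_tables)
    _write_tsv(records, outdir / "records.tsv")

    associations = {}
    for modality in modality_tables:
        result = associate(
            records, modality, permutation=cfg.permutation,
            n_perm=cfg.n_perm, seed=cfg.seed,
        )
        associations[modality] = result.to_dict()

    report = {
        "schema_version": 1,
        "n_sites": len(sites),
        "n_pairs": len(pairs),
        "pair_kinds": pairs_df["pair_kind"].value_counts().to_dict(),
        "associations": associations,
        "provenance": {
            "gliodist_version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
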