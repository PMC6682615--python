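"""Seed-reproducible synthetic multi-site tumor cohorts.

The generator emulates the study design the pipeline targets: per patient,
a handful of stereotactic biopsy sites inside a spherical tumor (radius
~30 mm), a share of needle cores split into shallow/deep sub-samples 5 mm
apart, and three molecular layers whose computed distances increase with
inter-site separation:

* mutations — a set of truncal mutations present in every sample at high
  allele frequency, plus "seeded subclone spheres": subclonal mutation
  clusters at random 3D loci with a spatial radius, carried only by the
  samples inside it, at lower AF. Read counts are drawn to satisfy the
  five retention criteria; labeled filter-failing decoys exercising each
  criterion can be mixed in.
* CNV — a patient-level base segmentation whose per-sample log2 values are
  perturbed with a standard deviation growing with the sample's distance
  from the tumor center; optional sample-specific breakpoints exercise the
  breakpoint-union step.
* methylation — a bimodal per-probe base beta profile; per-sample
  deviations are drawn from a spatially correlated Gaussian field over the
  site coordinates (squared-exponential kernel) on the logit scale, so
  beta values stay in [0, 1] without clipping and nearby sites stay
  similar.

Each patient draws from its own RNG streams derived from (master seed,
patient index, layer), so cohorts are extensible without perturbing
existing patients and identical seeds reproduce outputs bit-for-bit.

A separate direct linear-model generator (:func:`simulate_distance_pairs`)
draws (Euclidean mm, genomic distance) pairs straight from a target line
``y = a + b x`` plus Gaussian noise, truncated at 0; it backs the
parameter-recovery checks with the published regression constants as
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import study
from .cohort import BiopsySite
from .cnv import CNVSegment, write_cns
from .methylation import BetaMatrix, write_beta_matrix
from .mutations import VariantCall, write_variant_table


@dataclass
class MutationModel:
    n_truncal: int = 10
    truncal_af_mean: float = 0.40
    truncal_af_sd: float = 0.08
    subclone_rate_per_mm: float = 0.3
    muts_per_subclone_mean: float = 3.0
    private_af_mean: float = 0.20
    private_af_sd: float = 0.05
    read_depth: float = 100.0
    decoy_fraction: float = 0.2


@dataclass
class CNVModel:
    n_segments: int = 40
    base_log2_sd: float = 0.4
    zero_fraction: float = 0.4
    perturbation_sd_per_mm: float = 0.01
    field_length_scale_mm: float = 10.0
    extra_breakpoint_prob: float = 0.2


@dataclass
class MethylationModel:
    n_probes: int = 10000
    field_length_scale_mm: float = 10.0
    field_sd: float = 0.5
    missing_rate: float = 0.005


@dataclass
class LinearTarget:
    """Ground-truth line for the direct (x, y) pair generator.

    ``x_range`` is restricted to where intercept + slope * x stays well
    above 0, because y is truncated at 0 for metric validity and ordinary
    least squares is biased wherever truncation is active.
    """

    intercept: float
    slope: float
    noise_sd: float
    x_range: tuple[float, float]


DEFAULT_LINEAR_TARGETS: dict[str, LinearTarget] = {
    "mutation": LinearTarget(study.MUTATION_INTERCEPT, study.MUTATION_SLOPE_PER_MM, 3.0, (10.0, 30.0)),
    "cnv": LinearTarget(study.CNV_INTERCEPT, study.CNV_SLOPE_PER_MM, 10.0, (16.0, 30.0)),
    "methylation": LinearTarget(study.METHYLATION_INTERCEPT, study.METHYLATION_SLOPE_PER_MM, 0.5, (5.0, 30.0)),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 23
    sites_per_patient: tuple[int, int] = (2, 4)
    tumor_radius_mm: float = 30.0
    shallow_deep_fraction: float = 0.5
    mutation: MutationModel = field(default_factory=MutationModel)
    cnv: CNVModel = field(default_factory=CNVModel)
    methylation: MethylationModel = field(default_factory=MethylationModel)

    def __post_init__(self) -> None:
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if not 0 <= self.shallow_deep_fraction <= 1:
            raise ValueError("shallow_deep_fraction must lie in [0, 1]")


def _rng(cfg: SimulationConfig, patient_index: int, layer: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, patient_index, layer])


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    return direction * radius * rng.random() ** (1.0 / 3.0)


def _patient_ids(cfg: SimulationConfig) -> list[str]:
    return [f"P{p + 1:02d}" for p in range(cfg.n_patients)]


def simulate_coordinates(cfg: SimulationConfig) -> list[BiopsySite]:
    """Biopsy sites uniform within a sphere; some needle cores split 5 mm."""
    sites: list[BiopsySite] = []
    lo, hi = cfg.sites_per_patient
    for p, patient_id in enumerate(_patient_ids(cfg)):
        rng = _rng(cfg, p, 0)
        n_sources = int(rng.integers(lo, hi + 1))
        sample_no = 0
        for t in range(n_sources):
            pos = _uniform_in_sphere(rng, cfg.tumor_radius_mm)
            source_id = f"{patient_id}T{t + 1}"
            if rng.random() < cfg.shallow_deep_fraction:
                axis = rng.standard_normal(3)
                axis /= np.linalg.norm(axis)
                deep = pos + 5.0 * axis
                for label, xyz in (("shallow", pos), ("deep", deep)):
                    sample_no += 1
                    sites.append(
                        BiopsySite(
                            patient_id=patient_id,
                            sample_id=f"{patient_id}S{sample_no}",
                            x=float(xyz[0]),
                            y=float(xyz[1]),
                            z=float(xyz[2]),
                            instrument="needle",
                            depth_label=label,
                            source_site_id=source_id,
                        )
                    )
            else:
                sample_no += 1
                instrument = "forceps" if rng.random() < 0.5 else "needle"
                sites.append(
                    BiopsySite(
                        patient_id=patient_id,
                        sample_id=f"{patient_id}S{sample_no}",
                        x=float(pos[0]),
                        y=float(pos[1]),
                        z=float(pos[2]),
                        instrument=instrument,
                        depth_label="whole",
                        source_site_id=source_id,
                    )
                )
    return sites


_BASES = ("A", "C", "G", "T")


def _random_key(rng: np.random.Generator, used: set) -> tuple[str, int, str, str]:
    while True:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(100_000, 100_000_000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = (chrom, pos, str(ref), str(alt))
        if key not in used:
            used.add(key)
            return key


def _passing_counts(rng: np.random.Generator, af: float, depth_mean: float) -> tuple[int, int]:
    depth = max(40, int(rng.poisson(depth_mean)))
    alt = max(8, int(round(af * depth)))
    ref = max(10, depth - alt)
    return ref, alt


def simulate_mutations(
    cfg: SimulationConfig, sites: list[BiopsySite]
) -> tuple[list[VariantCall], dict]:
    """Truncal + subclone-sphere mutations with filter-consistent reads.

    Returns the calls plus a ground-truth dict with the intended-pass and
    decoy call identities (patient, sample, chrom, pos, ref, alt) so the
    retention filter can be validated against construction labels.
    """
    model = cfg.mutation
    by_patient: dict[str, list[BiopsySite]] = {}
    for s in sites:
        by_patient.setdefault(s.patient_id, []).append(s)

    calls: list[VariantCall] = []
    truth = {"intended_pass": [], "decoys": []}
    for p, patient_id in enumerate(sorted(by_patient)):
        rng = _rng(cfg, p, 1)
        patient_sites = by_patient[patient_id]
        used_keys: set = set()
        pass_calls: list[VariantCall] = []

        def add_call(sample_id: str, key, counts: tuple[int, int]) -> None:
            pass_calls.append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    region_class="exonic",
                    func_class="nonsynonymous SNV",
                    ref_reads=counts[0],
                    alt_reads=counts[1],
                )
            )

        # truncal mutations predate subclone divergence: one patient-level
        # AF (and read-count draw) per mutation, identical in every sample,
        # so a cohort without subclones has exactly zero mutation distance
        for _ in range(model.n_truncal):
            key = _random_key(rng, used_keys)
            af = float(np.clip(rng.normal(model.truncal_af_mean, model.truncal_af_sd), 0.12, 0.95))
            counts = _passing_counts(rng, af, model.read_depth)
            for site in patient_sites:
                add_call(site.sample_id, key, counts)

        n_subclones = int(rng.poisson(model.subclone_rate_per_mm * cfg.tumor_radius_mm))
        for _ in range(n_subclones):
            center = _uniform_in_sphere(rng, cfg.tumor_radius_mm)
            radius = float(rng.uniform(0.15, 0.6)) * cfg.tumor_radius_mm
            members = [
                s
                for s in patient_sites
                if s.has_coordinates
                and np.linalg.norm(np.array(s.coordinates) - center) <= radius
            ]
            if not members:
                continue
            n_muts = 1 + int(rng.poisson(model.muts_per_subclone_mean))
            for _ in range(n_muts):
                key = _random_key(rng, used_keys)
                for site in members:
                    af = float(np.clip(rng.normal(model.private_af_mean, model.private_af_sd), 0.105, 0.6))
                    add_call(site.sample_id, key, _passing_counts(rng, af, model.read_depth))

        calls.extend(pass_calls)
        truth["intended_pass"].extend(
            [c.patient_id, c.sample_id, c.chrom, c.pos, c.ref, c.alt] for c in pass_calls
        )

        # decoys: one violated criterion each, cycling through the five
        decoy_modes = [
            dict(region_class="intronic", func_class="nonsynonymous SNV", ref_reads=50, alt_reads=12),
            dict(region_class="exonic", func_class="synonymous SNV", ref_reads=50, alt_reads=12),
            dict(region_class="exonic", func_class="nonsynonymous SNV", ref_reads=5, alt_reads=20),
            dict(region_class="exonic", func_class="nonsynonymous SNV", ref_reads=35, alt_reads=7),
            dict(region_class="exonic", func_class="nonsynonymous SNV", ref_reads=152, alt_reads=8),
        ]
        n_decoys = int(round(model.decoy_fraction * len(pass_calls)))
        for d in range(n_decoys):
            key = _random_key(rng, used_keys)
            site = patient_sites[int(rng.integers(len(patient_sites)))]
            mode = decoy_modes[d % len(decoy_modes)]
            decoy = VariantCall(
                patient_id=patient_id,
                sample_id=site.sample_id,
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                **mode,
            )
            calls.append(decoy)
            truth["decoys"].append(
                [decoy.patient_id, decoy.sample_id, decoy.chrom, decoy.pos, decoy.ref, decoy.alt]
            )
    return calls, truth


_CHROM_LENGTHS = {"chr1": 120_000_000, "chr2": 100_000_000, "chr3": 90_000_000, "chr4": 80_000_000}


def simulate_cnv(cfg: SimulationConfig, sites: list[BiopsySite]) -> list[CNVSegment]:
    """Base segmentation plus a spatially correlated log2 perturbation field.

    Per base segment, the samples' deviations are drawn jointly from a
    Gaussian field whose per-sample standard deviation grows with that
    sample's distance from the tumor center (``perturbation_sd_per_mm``)
    and whose cross-sample correlation decays with inter-site separation
    (squared-exponential, ``field_length_scale_mm``) — so nearby samples
    carry similar profiles and the pairwise Canberra distance grows with
    pair separation.
    """
    model = cfg.cnv
    by_patient: dict[str, list[BiopsySite]] = {}
    for s in sites:
        by_patient.setdefault(s.patient_id, []).append(s)

    segments: list[CNVSegment] = []
    chroms = list(_CHROM_LENGTHS)
    total_len = sum(_CHROM_LENGTHS.values())
    for p, patient_id in enumerate(sorted(by_patient)):
        rng = _rng(cfg, p, 2)
        patient_sites = by_patient[patient_id]
        n_sites = len(patient_sites)

        # patient-level base segmentation and log2 profile
        base: list[tuple[str, int, int, float]] = []
        for chrom in chroms:
            length = _CHROM_LENGTHS[chrom]
            n_seg = max(1, round(model.n_segments * length / total_len))
            internal = (
                np.sort(np.unique(rng.integers(1_000, length - 1_000, size=n_seg - 1)))
                if n_seg > 1
                else np.array([], dtype=int)
            )
            bounds = [0, *internal.tolist(), length]
            for lo, hi in zip(bounds, bounds[1:]):
                if rng.random() < model.zero_fraction:
                    log2 = 0.0
                else:
                    log2 = float(rng.normal(0.0, model.base_log2_sd))
                base.append((chrom, int(lo), int(hi), log2))

        coords = np.array(
            [s.coordinates if s.has_coordinates else (0.0, 0.0, 0.0) for s in patient_sites]
        )
        sds = model.perturbation_sd_per_mm * np.linalg.norm(coords, axis=1)
        if np.any(sds > 0):
            d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            corr = np.exp(-d2 / (2.0 * model.field_length_scale_mm**2))
            cov = np.outer(sds, sds) * corr + 1e-9 * np.eye(n_sites)
            chol = np.linalg.cholesky(cov)
            dev = rng.standard_normal((len(base), n_sites)) @ chol.T
        else:
            dev = np.zeros((len(base), n_sites))

        for j, site in enumerate(patient_sites):
            for i, (chrom, lo, hi, log2) in enumerate(base):
                value = log2 + float(dev[i, j])
                if rng.random() < model.extra_breakpoint_prob and hi - lo > 2_000:
                    split = int(rng.integers(lo + 1_000, hi - 1_000))
                    jitter = float(rng.normal(0.0, sds[j])) if sds[j] > 0 else 0.0
                    segments.append(CNVSegment(patient_id, site.sample_id, chrom, lo, split, value))
                    segments.append(
                        CNVSegment(patient_id, site.sample_id, chrom, split, hi, value + jitter)
                    )
                else:
                    segments.append(CNVSegment(patient_id, site.sample_id, chrom, lo, hi, value))
    return segments


def simulate_methylation(cfg: SimulationConfig, sites: list[BiopsySite]) -> BetaMatrix:
    """Spatially correlated beta profiles on the logit scale.

    Per-sample deviations from the patient's base profile come from a
    Gaussian field with squared-exponential covariance over the site
    coordinates, so the expected L1 distance between two samples grows
    with their separation (up to the field's length scale).
    """
    model = cfg.methylation
    probe_ids = [f"cg{i:08d}" for i in range(model.n_probes)]
    by_patient: dict[str, list[BiopsySite]] = {}
    for s in sites:
        by_patient.setdefault(s.patient_id, []).append(s)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for p, patient_id in enumerate(sorted(by_patient)):
        rng = _rng(cfg, p, 3)
        patient_sites = by_patient[patient_id]
        n_sites = len(patient_sites)

        bimodal = rng.random(model.n_probes) < 0.5
        base = np.where(
            bimodal, rng.beta(1.0, 9.0, model.n_probes), rng.beta(9.0, 1.0, model.n_probes)
        )
        base = np.clip(base, 0.01, 0.99)

        if model.field_sd > 0:
            coords = np.array([s.coordinates for s in patient_sites])
            d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
            cov = model.field_sd**2 * np.exp(-d2 / (2.0 * model.field_length_scale_mm**2))
            cov += 1e-9 * np.eye(n_sites)
            chol = np.linalg.cholesky(cov)
            dev = rng.standard_normal((model.n_probes, n_sites)) @ chol.T
        else:
            dev = np.zeros((model.n_probes, n_sites))

        beta = expit(logit(base)[:, None] + dev)
        if model.missing_rate > 0:
            beta[rng.random(beta.shape) < model.missing_rate] = np.nan
        idh = "mutant" if rng.random() < 0.5 else "wildtype"
        for j, site in enumerate(patient_sites):
            columns[site.sample_id] = beta[:, j]
            meta_rows.append({"sample_id": site.sample_id, "patient_id": patient_id, "idh": idh})

    beta_df = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return BetaMatrix(beta_df, meta)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    sites: list[BiopsySite]
    calls: list[VariantCall]
    mutation_truth: dict
    segments: list[CNVSegment]
    beta: BetaMatrix


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate all layers for one cohort (deterministic under the seed)."""
    sites = simulate_coordinates(cfg)
    calls, truth = simulate_mutations(cfg, sites)
    segments = simulate_cnv(cfg, sites)
    beta = simulate_methylation(cfg, sites)
    return SyntheticCohort(cfg, sites, calls, truth, segments, beta)


def simulate_distance_pairs(
    intercept: float,
    slope: float,
    noise_sd: float,
    n: int,
    x_range: tuple[float, float] = (5.0, 30.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw (euclidean_mm, genomic_distance) pairs from a target line.

    y = intercept + slope * x + N(0, noise_sd), truncated at 0 so the
    result is a valid distance.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.0)
    return pd.DataFrame({"euclidean_mm": x, "genomic_distance": y})


def simulate_linear_cohort(
    targets: dict[str, LinearTarget] | None = None,
    n_patients: int = 25,
    pairs_per_patient: tuple[int, int] = (1, 10),
    seed: int = 0,
) -> pd.DataFrame:
    """A pooled multi-patient record table drawn from the target lines.

    For each patient and each modality, a random number of biopsy pairs is
    drawn from that modality's ground-truth line. Returns association-ready
    records (patient_id, sample_a, sample_b, euclidean_mm, modality,
    genomic_distance).
    """
    targets = targets or DEFAULT_LINEAR_TARGETS
    frames = []
    for p in range(n_patients):
        patient_id = f"P{p + 1:02d}"
        rng = np.random.default_rng([seed, p, 9])
        n_pairs = int(rng.integers(pairs_per_patient[0], pairs_per_patient[1] + 1))
        if n_pairs < 1:
            continue
        for modality, t in targets.items():
            df = simulate_distance_pairs(
                t.intercept, t.slope, t.noise_sd, max(n_pairs, 3), t.x_range, rng
            ).iloc[:n_pairs]
            df = df.assign(
                patient_id=patient_id,
                sample_a=[f"{patient_id}S{2 * i + 1}" for i in range(len(df))],
                sample_b=[f"{patient_id}S{2 * i + 2}" for i in range(len(df))],
                modality=modality,
            )
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["patient_id", "sample_a", "sample_b", "euclidean_mm", "modality", "genomic_distance"]]


def three_sample_example() -> list[VariantCall]:
    """The canonical three-sample sharing fixture.

    Ten truncal mutations carried by all three samples at high AF plus one
    private mutation each in the first and third sample at lower AF — the
    pattern whose sharing tree has trunk length 10 and tip branches 1/0/1.
    """
    samples = ["P1S1", "P1S2", "P1S3"]
    calls: list[VariantCall] = []
    for i in range(10):
        for s in samples:
            calls.append(
                VariantCall(
                    patient_id="P1",
                    sample_id=s,
                    chrom="chr1",
                    pos=1_000_000 + i,
                    ref="A",
                    alt="G",
                    ref_reads=60,
                    alt_reads=40,
                )
            )
    for s, pos in (("P1S1", 2_000_000), ("P1S3", 2_000_001)):
        calls.append(
            VariantCall(
                patient_id="P1",
                sample_id=s,
                chrom="chr2",
                pos=pos,
                ref="C",
                alt="T",
                ref_reads=80,
                alt_reads=20,
            )
        )
    return calls


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the full synthetic input set as plain-text files.

    Produces coordinates TSV, long-format variant TSV, per-sample
    ``.cns``-style segment TSVs, the beta matrix CSV, the sample metadata
    TSV and a ground-truth JSON (generator config plus per-call labels).
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "coordinates": str(outdir / "coordinates.tsv"),
        "variants": str(outdir / "variants.tsv"),
        "cnv_dir": str(outdir / "cns"),
        "beta": str(outdir / "beta.csv"),
        "sample_meta": str(outdir / "samples.tsv"),
        "truth": str(outdir / "truth.json"),
    }

    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "sample_id": s.sample_id,
                "x_mm": s.x,
                "y_mm": s.y,
                "z_mm": s.z,
                "instrument": s.instrument,
                "depth_label": s.depth_label,
                "source_site_id": s.source_site_id or "",
            }
            for s in cohort.sites
        ]
    ).to_csv(paths["coordinates"], sep="\t", index=False, float_format="%.4f")

    write_variant_table(cohort.calls, paths["variants"])

    cns_dir = Path(paths["cnv_dir"])
    cns_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[CNVSegment]] = {}
    for seg in cohort.segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    for sample_id, segs in by_sample.items():
        write_cns(segs, cns_dir / f"{sample_id}.cns")

    write_beta_matrix(cohort.beta, paths["beta"], paths["sample_meta"])

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": asdict(cohort.config),
                "mutation_truth": cohort.mutation_truth,
                "linear_targets": {k: asdict(v) for k, v in DEFAULT_LINEAR_TARGETS.items()},
            },
            fh,
            indent=1,
        )
    return paths
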