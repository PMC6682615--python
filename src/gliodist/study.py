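"""Reference constants for the multi-site glioma biopsy study design.

The cohort this package models comprises 23 glioma patients, each with two
to six stereotactically localized biopsy samples that passed methylation
quality control with usable image coordinates, yielding 77 unique
intra-patient biopsy pairs. ``REFERENCE_PAIR_COUNTS`` lists the published
per-patient pair counts; ``reference_cohort_sites`` rebuilds a coordinate
cohort with exactly that pair structure so the accounting can be recomputed
from the pair-enumeration code rather than asserted.

``EXOME_SIZE_MB`` and ``BACKGROUND_MUTATION_RATE_PER_MB`` parameterize the
hypermutation reference burden: lower-grade gliomas carry a median somatic
mutation rate under 1 per Mb, so an ~30 Mb exome is expected to carry fewer
than ~30 filtered mutations; samples far above that are hypermutation
candidates.
"""

from __future__ import annotations

import math

from .cohort import BiopsySite

# Published per-patient intra-tumor pair counts (patients 1..23). Each count
# is C(n, 2) for n coordinate-usable samples; patient 4 contributed six
# biopsies but only five with unambiguous coordinates (10 pairs).
REFERENCE_PAIR_COUNTS: tuple[int, ...] = (
    3, 1, 1, 10, 6, 1, 6, 6, 6, 3, 1, 3, 1, 15, 1, 1, 1, 1, 1, 1, 1, 1, 6,
)

EXOME_SIZE_MB: float = 30.0
BACKGROUND_MUTATION_RATE_PER_MB: float = 1.0

# Printed best-fit regression constants (genomic distance = a + b * mm):
# used as ground-truth defaults for the linear synthetic generator.
MUTATION_SLOPE_PER_MM: float = 1.7
MUTATION_INTERCEPT: float = -11.6
CNV_SLOPE_PER_MM: float = 6.9
CNV_INTERCEPT: float = -93.8
METHYLATION_SLOPE_PER_MM: float = 0.18
METHYLATION_INTERCEPT: float = 5.27


def _n_samples_for_pairs(n_pairs: int) -> int:
    """Invert C(n, 2) = n_pairs for integer n >= 2."""
    n = int(round((1 + math.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise ValueError(f"{n_pairs} is not a binomial(n, 2) count")
    return n


def reference_cohort_sites() -> list[BiopsySite]:
    """Build a placeholder-coordinate cohort with the reference pair structure.

    Coordinates are synthetic (sample index along one axis); only the pair
    *counts* are meaningful, matching the published per-patient accounting.
    """
    sites: list[BiopsySite] = []
    for p, n_pairs in enumerate(REFERENCE_PAIR_COUNTS, start=1):
        n_samples = _n_samples_for_pairs(n_pairs)
        for s in range(1, n_samples + 1):
            sites.append(
                BiopsySite(
                    patient_id=f"P{p:02d}",
                    sample_id=f"P{p:02d}S{s}",
                    x=float(5 * s),
                    y=0.0,
                    z=0.0,
                )
            )
    return sites


def hypermutation_reference_count(
    exome_size_mb: float = EXOME_SIZE_MB,
    rate_per_mb: float = BACKGROUND_MUTATION_RATE_PER_MB,
) -> float:
    """Expected exome-wide mutation burden at the background rate."""
    return exome_size_mb * rate_per_mb
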