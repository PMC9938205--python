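"""Genome-bin quality metrics for ultra-small prokaryotes.

Completeness and contamination of CPR (Patescibacteria), Dependentiae and
DPANN bins are assessed from lineage-specific single-copy gene (SCG) sets:
51 bacterial markers for Dependentiae, 43 for Patescibacteria and 38
archaeal markers for DPANN.  Because reduced genomes lack many universal
markers, completeness is simply the fraction of the lineage's markers
present and contamination the fraction present in more than one copy.

Estimated genome size corrects the assembled bin size for incompleteness
and redundant contigs::

    estimated_size = (bin_size - bin_size * contamination) / completeness

Samples are classed on dissolved oxygen (DO, g/m^3): oxic strictly above
3, with configurable lower boundaries for dysoxic, suboxic and anoxic
groundwater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Marker-set sizes for the lineage-specific SCG collections.
SCG_SET_SIZES: dict[str, int] = {"bact51": 51, "bact43": 43, "arch38": 38}

#: Lineage group -> SCG set used for its quality assessment.
GROUP_SCG_SET: dict[str, str] = {
    "Patescibacteria": "bact43",
    "Dependentiae": "bact51",
    "DPANN-Nanoarchaeota": "arch38",
    "DPANN-Micrarchaeota": "arch38",
    "DPANN-Altiarchaeota": "arch38",
    "other": "bact51",
}

#: Lineage groups regarded as ultra-small prokaryotes.
ULTRASMALL_GROUPS: tuple[str, ...] = (
    "Patescibacteria",
    "Dependentiae",
    "DPANN-Nanoarchaeota",
    "DPANN-Micrarchaeota",
    "DPANN-Altiarchaeota",
)


class SchemaError(ValueError):
    """Raised when an input table or profile violates its declared schema."""


@dataclass
class ScgProfile:
    """Single-copy-gene copy numbers for one genome bin.

    Parameters
    ----------
    mag_id : str
        Genome bin identifier.
    scg_counts : mapping of str to int
        Copy number per marker; absent markers may be omitted.
    scg_set : {"bact51", "bact43", "arch38"}
        Which lineage marker collection the profile is scored against.
    """

    mag_id: str
    scg_counts: Mapping[str, int] = field(default_factory=dict)
    scg_set: str = "bact43"

    def __post_init__(self) -> None:
        if self.scg_set not in SCG_SET_SIZES:
            raise SchemaError(
                f"unknown SCG set {self.scg_set!r}; expected one of {sorted(SCG_SET_SIZES)}"
            )
        for marker, copies in self.scg_counts.items():
            if int(copies) != copies or copies < 0:
                raise SchemaError(
                    f"{self.mag_id}: marker {marker!r} has invalid copy number {copies!r}"
                )
        if len(self.scg_counts) > SCG_SET_SIZES[self.scg_set]:
            raise SchemaError(
                f"{self.mag_id}: {len(self.scg_counts)} markers exceed the "
                f"{self.scg_set} set size {SCG_SET_SIZES[self.scg_set]}"
            )


def scg_completeness(profile: ScgProfile) -> tuple[float, float]:
    """Completeness and contamination from an SCG profile.

    Completeness is the fraction of the marker set present at least once;
    contamination is the fraction present at least twice (duplicated
    markers, paralleling the CheckM convention).

    Returns
    -------
    (completeness, contamination) : tuple of float
        Both as fractions of the marker-set size, so contamination can
        never exceed completeness.
    """
    size = SCG_SET_SIZES[profile.scg_set]
    present = sum(1 for c in profile.scg_counts.values() if c >= 1)
    duplicated = sum(1 for c in profile.scg_counts.values() if c >= 2)
    return present / size, duplicated / size


def estimate_genome_size(
    bin_size: float, completeness: float, contamination: float
) -> float:
    """Estimated full genome size (bp) from bin size and quality.

    ``(bin_size - bin_size * contamination) / completeness`` — removes the
    redundant fraction, then scales up for the missing fraction.

    Raises
    ------
    ValueError
        If ``completeness`` is zero (the estimate is undefined) or inputs
        are out of range.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if not 0 < completeness <= 1:
        raise ValueError(
            f"completeness must be in (0, 1] for a defined estimate, got {completeness}"
        )
    if contamination < 0:
        raise ValueError(f"contamination must be >= 0, got {contamination}")
    return (bin_size - bin_size * contamination) / completeness


def genes_per_mbp(gene_count: int, estimated_size: float) -> float:
    """Gene density normalized to estimated genome size (copies per Mbp)."""
    if estimated_size <= 0:
        raise ValueError(f"estimated_size must be positive, got {estimated_size}")
    if gene_count < 0:
        raise ValueError(f"gene_count must be >= 0, got {gene_count}")
    return gene_count * 1_000_000 / estimated_size


# Redox class boundaries (g/m^3 DO).  Only the oxic bound (> 3, strict) is
# fixed by field convention; the lower boundaries are conventional defaults
# and applied as half-open intervals [low, high).
DEFAULT_REDOX_BOUNDS: dict[str, float] = {"anoxic_max": 0.1, "suboxic_max": 0.3, "oxic_min": 3.0}


def classify_redox(
    do_concentration: float,
    *,
    anoxic_max: float = 0.1,
    suboxic_max: float = 0.3,
    oxic_min: float = 3.0,
) -> str:
    """Classify a groundwater sample by dissolved oxygen.

    oxic iff DO > ``oxic_min`` (strict); below that, half-open bands
    [0, anoxic_max) anoxic, [anoxic_max, suboxic_max) suboxic, and
    [suboxic_max, oxic_min] dysoxic.
    """
    if do_concentration < 0:
        raise ValueError(f"DO concentration must be >= 0, got {do_concentration}")
    if not (0 < anoxic_max <= suboxic_max <= oxic_min):
        raise ValueError("redox boundaries must satisfy 0 < anoxic <= suboxic <= oxic")
    if do_concentration > oxic_min:
        return "oxic"
    if do_concentration >= suboxic_max:
        return "dysoxic"
    if do_concentration >= anoxic_max:
        return "suboxic"
    return "anoxic"


# Quality tiers with the inequality semantics as printed in the source
# conventions: completeness strictly above 50% / 70%, at or above 80% / 90%;
# contamination strictly below the cap for the tiers that state one.
QUALITY_TIERS: dict[int, tuple[float, bool, float | None]] = {
    # tier -> (completeness bound, inclusive?, contamination cap or None)
    50: (0.50, False, 0.05),
    70: (0.70, False, 0.05),
    80: (0.80, True, None),
    90: (0.90, True, None),
}


def quality_tiers(mags: pd.DataFrame) -> pd.DataFrame:
    """Boolean tier membership (columns ``tier50`` .. ``tier90``) per MAG.

    ``mags`` needs ``completeness`` and ``contamination`` columns (fractions).
    """
    out = pd.DataFrame(index=mags.index)
    comp = mags["completeness"].astype(float)
    cont = mags["contamination"].astype(float)
    for tier, (bound, inclusive, cap) in QUALITY_TIERS.items():
        ok = comp >= bound if inclusive else comp > bound
        if cap is not None:
            ok &= cont < cap
        out[f"tier{tier}"] = ok
    return out


def quality_filter(
    mags: pd.DataFrame,
    min_completeness: float = 0.5,
    max_contamination: float = 0.05,
    *,
    inclusive_completeness: bool = False,
) -> pd.DataFrame:
    """Subset of MAGs passing a completeness/contamination filter.

    Default semantics are strict on both sides (completeness > min,
    contamination < max), matching the ">50% complete, <5% contamination"
    convention for medium-quality reduced genomes.
    """
    if not (0 <= min_completeness <= 1 and 0 <= max_contamination <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    comp = mags["completeness"].astype(float)
    cont = mags["contamination"].astype(float)
    keep = (comp >= min_completeness) if inclusive_completeness else (comp > min_completeness)
    keep &= cont < max_contamination
    return mags.loc[keep]


def add_estimated_size(mags: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``mags`` with an ``estimated_size`` column (bp).

    MAGs with completeness 0 get NaN (undefined estimate) and a warning.
    """
    out = mags.copy()
    comp = out["completeness"].astype(float)
    cont = out["contamination"].astype(float)
    size = out["bin_size"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = (size - size * cont) / comp
    undefined = comp <= 0
    if undefined.any():
        logger.warning(
            "estimated size undefined for %d MAG(s) with completeness 0", int(undefined.sum())
        )
        est = est.where(~undefined)
    out["estimated_size"] = est
    return out
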