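"""Diet-report scoring: qualitative labels to proportions to profiles.

Literature diet reports come in two flavours: qualitative descriptions
("beetles are a major component of the diet") and quantitative proportions
("21% of prey items were beetles").  This module converts the four-level
qualitative vocabulary to calibrated proportions, merges the two report
types per species, and renormalizes so the per-species prey weights sum to
one — the weights that feed the prey-specificity statistic.  It also
computes diet class richness (number of distinct prey taxonomic classes,
out of a 12-class universe), the diet-breadth covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

from .errors import DomainError, MappingError, VocabularyError

#: Calibrated proportion of the diet assigned to each qualitative label.
LABEL_SCORES = {
    "major": 0.60,
    "common": 0.20,
    "uncommon": 0.05,
    "rare": 0.01,
}

#: Maximum number of prey taxonomic classes a diet may span.
MAX_DIET_CLASSES = 12

#: Slack allowed on a profile's total weight (profiles sum to 100% +/- 1%).
PROFILE_SUM_TOL = 0.01


def score_label(label: str) -> float:
    """Proportion of diet assigned to a qualitative abundance label.

    major -> 0.60, common -> 0.20, uncommon -> 0.05, rare -> 0.01.
    """
    key = label.strip().lower()
    if key not in LABEL_SCORES:
        raise VocabularyError(
            f"unknown diet label {label!r}; expected one of "
            f"{sorted(LABEL_SCORES)}"
        )
    return LABEL_SCORES[key]


@dataclass(frozen=True)
class QualitativeDietReport:
    """Qualitative prey-abundance labels for one predator species."""

    species: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, label in self.labels.items():
            score_label(label)  # raises VocabularyError on bad labels


@dataclass(frozen=True)
class QuantitativeDietReport:
    """Quantitative prey proportions for one predator species.

    The proportions may sum to less than one when a residual fraction was
    reported as unidentified "other" prey.
    """

    species: str
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, p in self.proportions.items():
            if not 0 <= p <= 1:
                raise DomainError(
                    f"proportion for {taxon!r} must be in [0, 1], got {p}"
                )
        if sum(self.proportions.values()) > 1 + PROFILE_SUM_TOL:
            raise DomainError(
                "quantitative proportions sum to more than 1"
            )

    @property
    def total(self) -> float:
        return sum(self.proportions.values())


@dataclass(frozen=True)
class DietProfile:
    """Normalized prey weights for one predator species.

    Weights are positive and sum to one within +/-0.01; they are the
    weights of the diet-weighted divergence statistic.
    """

    species: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.weights:
            raise DomainError("diet profile must contain at least one taxon")
        for taxon, w in self.weights.items():
            if not w > 0:
                raise DomainError(
                    f"weight for {taxon!r} must be > 0, got {w}"
                )
        total = sum(self.weights.values())
        if abs(total - 1.0) > PROFILE_SUM_TOL:
            raise DomainError(
                f"profile weights sum to {total}, outside 1 +/- "
                f"{PROFILE_SUM_TOL}"
            )

    def displayed(self, ndigits: int = 3) -> dict[str, float]:
        """Display weights truncated toward zero at ``ndigits`` decimals.

        Storage stays at full float precision; truncation is the convention
        of the published diet tables this echoes (e.g. 0.21/1.45 = 0.1448
        is shown as 0.144).
        """
        from math import floor

        scale = 10 ** ndigits
        return {
            t: floor(w * scale + 1e-9) / scale
            for t, w in self.weights.items()
        }

    def displayed_total(self, ndigits: int = 3) -> float:
        """Sum of the displayed (truncated) weights."""
        return round(sum(self.displayed(ndigits).values()), ndigits)


def combine_reports(
    qual: QualitativeDietReport | None,
    quant: QuantitativeDietReport | dict | None,
    calibrate: bool = True,
) -> dict[str, float]:
    """Merge qualitative and quantitative reports into unweighted estimates.

    Quantitative values win for any taxon that has one.  A taxon with only
    a qualitative label receives a calibrated score: when ``calibrate`` is
    true and some taxon of the same species carries both the same label and
    a quantitative value, that value (the mean, if several) is used for
    every qualitative-only taxon with the label; otherwise the label's
    default score applies.  The result intentionally does not sum to one —
    normalization is a separate step.
    """
    if (
        qual is not None
        and isinstance(quant, QuantitativeDietReport)
        and qual.species != quant.species
    ):
        raise DomainError(
            f"reports refer to different species: {qual.species!r} vs "
            f"{quant.species!r}"
        )
    labels = dict(qual.labels) if qual is not None else {}
    if quant is None:
        props = {}
    elif isinstance(quant, QuantitativeDietReport):
        props = dict(quant.proportions)
    else:
        # a raw estimate mapping, e.g. re-applying combined estimates
        props = dict(quant)
    if not labels and not props:
        raise DomainError("both reports are empty")

    calibration: dict[str, float] = {}
    if calibrate:
        by_label: dict[str, list[float]] = {}
        for taxon, label in labels.items():
            if taxon in props:
                by_label.setdefault(label.strip().lower(), []).append(
                    props[taxon]
                )
        calibration = {lab: mean(vals) for lab, vals in by_label.items()}

    estimates: dict[str, float] = {}
    for taxon in list(props) + [t for t in labels if t not in props]:
        if taxon in props:
            estimates[taxon] = props[taxon]
        else:
            key = labels[taxon].strip().lower()
            score_label(key)
            estimates[taxon] = calibration.get(key, LABEL_SCORES[key])
    return estimates


def normalize_profile(
    estimates: dict[str, float], species: str = ""
) -> DietProfile:
    """Divide each unweighted estimate by the total so weights sum to one."""
    total = sum(estimates.values())
    if total <= 0:
        raise DomainError("cannot normalize: estimates sum to zero")
    weights = {t: v / total for t, v in estimates.items() if v > 0}
    if not weights:
        raise DomainError("cannot normalize: no positive estimates")
    return DietProfile(species=species, weights=weights)


def diet_class_richness(
    profile: DietProfile, class_map: dict[str, str]
) -> int:
    """Number of distinct prey classes carrying positive weight.

    Every profile taxon must have a class-map entry; richness above the
    12-class universe is rejected.
    """
    classes = set()
    for taxon, w in profile.weights.items():
        if taxon not in class_map:
            raise MappingError(taxon)
        if w > 0:
            classes.add(class_map[taxon])
    n = len(classes)
    if n > MAX_DIET_CLASSES:
        raise DomainError(
            f"diet spans {n} classes, exceeding the {MAX_DIET_CLASSES}-class "
            "universe"
        )
    return n


def infer_profile_from(
    donor: DietProfile, recipient_species: str
) -> DietProfile:
    """Copy a congener's profile onto a species with no usable diet data.

    The donor must be named explicitly; no automatic relative-finding is
    attempted.
    """
    return DietProfile(species=recipient_species, weights=dict(donor.weights))


def reports_to_profiles(rows, calibrate: bool = True) -> dict[str, DietProfile]:
    """Build per-species profiles from raw diet-report rows.

    ``rows`` are :class:`~venomphylo.data_io.DietReportRow` records; rows
    for the same species are gathered into one qualitative and one
    quantitative report, combined and normalized.
    """
    by_species: dict[str, tuple[dict, dict]] = {}
    for r in rows:
        labels, props = by_species.setdefault(r.species, ({}, {}))
        if r.qual_label is not None:
            labels[r.prey_taxon] = r.qual_label
        if r.quant_proportion is not None:
            props[r.prey_taxon] = r.quant_proportion
    profiles = {}
    for species, (labels, props) in by_species.items():
        est = combine_reports(
            QualitativeDietReport(species, labels) if labels else None,
            QuantitativeDietReport(species, props) if props else None,
            calibrate=calibrate,
        )
        profiles[species] = normalize_profile(est, species=species)
    return profiles
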