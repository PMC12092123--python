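"""Diet-weighted divergence between an assay model and natural prey.

The prey-specificity statistic D is the mean divergence time between the
organism a venom was assayed on and the predator's natural prey taxa,
weighted by each taxon's share of the diet.  Divergence is the age of the
most recent common ancestor on a time-calibrated ultrametric tree — the
convention of divergence-time databases — reported in hundreds of millions
of years (Hmya).  Small D means the venom was tested on something close to
what the predator actually eats.

Prey taxa recorded at class/order rank resolve to the named clade on the
reference tree; a model organism that is itself a member of the prey clade
is at divergence 0 from it (within-clade distances are unobservable at the
rank resolution of diet data).
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import CalibratedPhylogeny
from .diet_scoring import DietProfile
from .errors import TaxonLookupError

#: Myr per Hmya (divergence times are reported in hundreds of Myr).
MYR_PER_HMYA = 100.0


@dataclass(frozen=True)
class PreyContribution:
    """One prey taxon's share of the statistic."""

    taxon: str
    weight: float
    divergence_hmya: float


@dataclass(frozen=True)
class PreySpecificityResult:
    """D and its per-prey decomposition for one predator/model pair."""

    species: str
    model_organism: str
    d_hmya: float
    contributions: tuple[PreyContribution, ...]


def divergence_time(
    tree: CalibratedPhylogeny,
    taxon_a: str,
    taxon_b: str,
    metric: str = "mrca_age",
) -> float:
    """Time since two taxa diverged, in Hmya.

    ``metric="mrca_age"`` (default) returns the age of the most recent
    common ancestor; ``metric="patristic"`` returns the tip-to-tip path
    length, twice the MRCA age on an ultrametric tree.  Symmetric in its
    arguments.  Taxa may be tips or named internal clades; nested taxa
    (one a member of the other) are at divergence 0.
    """
    if metric not in ("mrca_age", "patristic"):
        raise ValueError(f"unknown metric {metric!r}")
    tree.require_ultrametric()
    node_a = tree.resolve(taxon_a)
    node_b = tree.resolve(taxon_b)
    if node_a is node_b or tree.is_nested(node_a, node_b):
        return 0.0
    age_myr = tree.depth - tree.mrca_depth(node_a, node_b)
    if metric == "patristic":
        age_myr *= 2.0
    return age_myr / MYR_PER_HMYA


def d_ld50_diet(
    tree: CalibratedPhylogeny,
    profile: DietProfile,
    model_taxon: str,
    metric: str = "mrca_age",
) -> PreySpecificityResult:
    """Diet-weighted mean divergence between the assay model and prey.

    Weights are renormalized to sum exactly to one (profiles carry up to
    +/-1% slack), so D is a true weighted mean of the per-prey divergence
    times and lies between the smallest and largest of them.
    """
    missing = []
    for taxon in profile.weights:
        try:
            tree.resolve(taxon)
        except TaxonLookupError:
            missing.append(taxon)
    if missing:
        raise TaxonLookupError(missing)

    total = sum(profile.weights.values())
    contributions = []
    d = 0.0
    for taxon, w in profile.weights.items():
        weight = w / total
        div = divergence_time(tree, model_taxon, taxon, metric=metric)
        contributions.append(PreyContribution(taxon, weight, div))
        d += weight * div
    return PreySpecificityResult(
        species=profile.species,
        model_organism=model_taxon,
        d_hmya=d,
        contributions=tuple(contributions),
    )
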