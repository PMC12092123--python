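"""Synthetic datasets with known ground truth for every pipeline stage.

Generates calibrated Yule trees, Dirichlet diet profiles over the 12-class
prey universe, body-size traits, repeated LD50 assays drawn from the same
generative model the mixed model fits (phylogenetic + species + residual
variance components, diet-weighted divergence as a fixed effect), venom
yields scaling with mass at a known exponent, and binary traits evolved
under the ER Mk process.  Default shapes mirror the comparative dataset
this emulates: 75 species, ~153 LD50 measures across 64 species, 60 yield
measures across 47 species.

Every generator is deterministic given its seed; a dataset-level seed is
split into fixed per-component sub-streams so adding one component never
perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CalibratedPhylogeny, read_newick
from .diet_scoring import DietProfile
from .errors import DomainError
from .prey_specificity import d_ld50_diet

# ---------------------------------------------------------------------------
# Prey reference tree (illustrative, not authoritative)
# ---------------------------------------------------------------------------

#: The 12 prey taxonomic classes a diet may span.
PREY_CLASSES = (
    "Insecta", "Arachnida", "Malacostraca", "Diplopoda", "Chilopoda",
    "Gastropoda", "Opisthopora", "Osteichthyes", "Amphibia", "Squamata",
    "Aves", "Mammalia",
)

#: Calibrated reference tree over the prey classes plus common assay model
#: organisms (branch lengths in Myr).  Depths are loosely patterned on
#: published arthropod/vertebrate divergence timescales and serve as an
#: illustrative stand-in for database-derived divergence times.
PREY_REFERENCE_NEWICK = (
    "((((((Acheta_domesticus:350,Musca_domestica:350)Insecta:100,"
    "Malacostraca:450)Pancrustacea:60,(Diplopoda:440,Chilopoda:440)"
    "Myriapoda:70)Mandibulata:70,Arachnida:580)Arthropoda:40,"
    "(Gastropoda:550,Opisthopora:550)Lophotrochozoa:70)Protostomia:80,"
    "(Osteichthyes:430,(Amphibia:352,((Mus_musculus:20,"
    "Rattus_norvegicus:20)Mammalia:299,(Squamata:280,Aves:280)"
    "Sauropsida:39)Amniota:33)Tetrapoda:78)Vertebrata:270);"
)

#: Assay model organisms and the injection routes used with each.
MODEL_ORGANISMS = {
    "Mus musculus": ("IP", "IV", "SC"),
    "Acheta domesticus": ("thorax_cephalothorax", "abdomen"),
    "Musca domestica": ("thorax_cephalothorax", "abdomen"),
}


def prey_reference_tree() -> CalibratedPhylogeny:
    """The packaged prey-class reference tree."""
    return read_newick(PREY_REFERENCE_NEWICK)


def prey_class_map() -> dict[str, str]:
    """Identity class map over the 12-class prey universe."""
    return {c: c for c in PREY_CLASSES}


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a synthetic dataset.

    Effect sizes are anchored to the magnitudes the comparative analysis
    reports: slope 0.4 on the diet-weighted divergence D (per Hmya),
    thorax/abdomen route contrasts 2.01 and 1.01 against the IP baseline,
    and a 0.75 yield-scaling exponent.  Mass and silk effects default to
    zero (no trade-off).  Variance components are sized so every component
    is estimable at ~150 observations.
    """

    beta0: float = -0.5
    beta_d: float = 0.4
    beta_mass: float = 0.0
    beta_silk: float = 0.0
    route_contrasts: dict = field(default_factory=lambda: {
        "IP": 0.0, "IV": 0.0, "SC": 0.0,
        "thorax_cephalothorax": 2.01, "abdomen": 1.01,
    })
    sigma2_animal: float = 0.05
    sigma2_species: float = 0.10
    sigma2_resid: float = 0.25
    yield_exponent: float = 0.75
    yield_intercept: float = 0.0
    yield_noise_sd: float = 0.3
    mk_rate: float = 0.004
    seed: int = 0


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


class _YuleNode:
    __slots__ = ("birth", "children", "name")

    def __init__(self, birth: float):
        self.birth = birth
        self.children = None
        self.name = None


def simulate_tree(
    n_tips: int, seed, root_depth: float = 300.0
) -> CalibratedPhylogeny:
    """Pure-birth (Yule) tree rescaled to a fixed root depth (Myr).

    The crown split sits at the root; waiting times between speciations
    are exponential with rate proportional to the number of extant
    lineages.  The same seed always reproduces the same newick text.
    """
    if n_tips < 2:
        raise DomainError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    root = _YuleNode(0.0)
    left, right = _YuleNode(0.0), _YuleNode(0.0)
    root.children = (left, right)
    active = [left, right]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node = active.pop(i)
        a, b = _YuleNode(t), _YuleNode(t)
        node.children = (a, b)
        active.extend((a, b))
    total = t + rng.exponential(1.0 / n_tips)
    scale = root_depth / total

    counter = [0]

    def emit(node: _YuleNode) -> str:
        if node.children is None:
            counter[0] += 1
            label = f"sp{counter[0]:03d}"
            length = (total - node.birth) * scale
            return f"{label}:{length:.8f}"
        inner = ",".join(emit(c) for c in node.children)
        if node is root:
            return f"({inner})"
        length = (node.children[0].birth - node.birth) * scale
        return f"({inner}):{length:.8f}"

    return read_newick(emit(root) + ";")


# ---------------------------------------------------------------------------
# Diets
# ---------------------------------------------------------------------------


def simulate_diets(
    species_list,
    prey_taxa=PREY_CLASSES,
    concentration: float = 1.0,
    seed=None,
    mean_extra_taxa: float = 3.0,
) -> dict[str, DietProfile]:
    """Dirichlet diet profiles over per-species random prey subsets.

    Subset size is 1 + Poisson(``mean_extra_taxa``) capped at the prey
    universe, giving a median diet class richness of four under the
    defaults — matching the empirical median diet breadth.
    """
    prey = list(prey_taxa)
    if not prey:
        raise DomainError("need at least one prey taxon")
    rng = np.random.default_rng(seed)
    profiles = {}
    for sp in species_list:
        k = 1 + min(int(rng.poisson(mean_extra_taxa)), len(prey) - 1)
        chosen = rng.choice(len(prey), size=k, replace=False)
        w = rng.dirichlet(np.full(k, concentration))
        w = np.clip(w, 1e-12, None)
        w = w / w.sum()
        profiles[sp] = DietProfile(
            species=sp,
            weights={prey[int(i)]: float(v) for i, v in zip(chosen, w)},
        )
    return profiles


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_traits(
    species_list, seed=None, silk_states: dict | None = None
):
    """Body sizes (log-normal lengths), silk use and extraction methods.

    Returns a DataFrame with one row per species.  Mass follows the
    length^2.6 power law on the mm -> g scale.
    """
    from .allometry import length_to_mass

    rng = np.random.default_rng(seed)
    rows = []
    for sp in species_list:
        length = 10.0 ** rng.normal(1.0, 0.35)
        silk = (
            bool(silk_states[sp]) if silk_states is not None
            else bool(rng.integers(2))
        )
        method = ("electrical_stimulation", "direct_stimulation",
                  "gland_extraction")[int(rng.integers(3))]
        rows.append({
            "species": sp,
            "body_length_mm": length,
            "body_mass_g": length_to_mass(length),
            "silk_use": silk,
            "extraction_method": method,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LD50 assays
# ---------------------------------------------------------------------------


@dataclass
class LD50Simulation:
    """Simulated assay table plus the latent per-record design columns."""

    table: pd.DataFrame  # species, model_organism, route, ld50, covariates
    ground_truth: GroundTruth


def simulate_ld50(
    tree: CalibratedPhylogeny,
    diets: dict[str, DietProfile],
    traits: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
    seed=None,
    prey_tree: CalibratedPhylogeny | None = None,
    max_extra_assays: int = 4,
    p_extra: float = 0.35,
) -> LD50Simulation:
    """Draw repeated LD50 assays from the mixed-model generative process.

    log10 LD50 = b0 + b_D * D + b_mass * log10(mass) + b_silk * silk
    + route contrast + a + s + e, with the phylogenetic effect a drawn
    from N(0, sigma2_a * A) on the spider tree and D computed on the prey
    reference tree for the assay's model organism.  Each species receives
    1 + Binomial(4, 0.35) assays (mean ~2.4) with random model organisms
    and routes.
    """
    from .phylo_mixed_model import phylo_correlation_matrix

    gt = ground_truth or GroundTruth()
    rng = np.random.default_rng(seed)
    if prey_tree is None:
        prey_tree = prey_reference_tree()

    species = [sp for sp in diets if sp]
    a_mat = phylo_correlation_matrix(tree, species)
    chol = np.linalg.cholesky(a_mat + 1e-10 * np.eye(len(species)))
    a_eff = np.sqrt(gt.sigma2_animal) * (
        chol @ rng.standard_normal(len(species))
    )
    s_eff = np.sqrt(gt.sigma2_species) * rng.standard_normal(len(species))

    trait_by_sp = traits.set_index("species")
    models = list(MODEL_ORGANISMS)
    rows = []
    for i, sp in enumerate(species):
        n_assays = 1 + int(rng.binomial(max_extra_assays, p_extra))
        mass = float(trait_by_sp.loc[sp, "body_mass_g"])
        silk = bool(trait_by_sp.loc[sp, "silk_use"])
        for _ in range(n_assays):
            model = models[int(rng.integers(len(models)))]
            routes = MODEL_ORGANISMS[model]
            route = routes[int(rng.integers(len(routes)))]
            d = d_ld50_diet(prey_tree, diets[sp], model).d_hmya
            mu = (
                gt.beta0
                + gt.beta_d * d
                + gt.beta_mass * np.log10(mass)
                + gt.beta_silk * float(silk)
                + gt.route_contrasts[route]
                + a_eff[i]
                + s_eff[i]
            )
            log10_ld50 = mu + np.sqrt(gt.sigma2_resid) * (
                rng.standard_normal()
            )
            rows.append({
                "species": sp,
                "model_organism": model,
                "route": route,
                "d_ld50_diet": d,
                "log10_mass": np.log10(mass),
                "silk_use": int(silk),
                "log10_ld50": log10_ld50,
                "ld50_mg_per_kg": 10.0 ** log10_ld50,
            })
    return LD50Simulation(table=pd.DataFrame(rows), ground_truth=gt)


# ---------------------------------------------------------------------------
# Venom yields
# ---------------------------------------------------------------------------


def simulate_yield(
    traits: pd.DataFrame,
    exponent: float = 0.75,
    noise_sd: float = 0.3,
    seed=None,
    intercept: float = 0.0,
    n_measures: int | None = None,
) -> pd.DataFrame:
    """Venom yields scaling with body mass at a known exponent.

    log10 yield = intercept + exponent * log10(mass) + N(0, noise_sd^2).
    When ``n_measures`` exceeds the number of species, extra repeat
    measures are assigned to randomly chosen species.
    """
    rng = np.random.default_rng(seed)
    masses = traits.set_index("species")["body_mass_g"]
    species = list(masses.index)
    picks = list(species)
    if n_measures is not None:
        if n_measures < len(species):
            chosen = rng.choice(len(species), size=n_measures, replace=False)
            picks = [species[int(i)] for i in chosen]
        else:
            extra = rng.choice(len(species),
                               size=n_measures - len(species), replace=True)
            picks = species + [species[int(i)] for i in extra]
    rows = []
    for sp in picks:
        mass = float(masses[sp])
        ly = intercept + exponent * np.log10(mass) + rng.normal(0.0, noise_sd)
        rows.append({
            "species": sp,
            "body_mass_g": mass,
            "venom_yield_mg": 10.0 ** ly,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Discrete trait evolution
# ---------------------------------------------------------------------------


def simulate_binary_trait(
    tree: CalibratedPhylogeny, rate: float, seed=None
) -> dict[str, int]:
    """Evolve a 0/1 trait root-to-tip under the equal-rates Mk process.

    The root state is an equilibrium (fair) draw; along each branch of
    length t the state flips with probability (1 - exp(-2*rate*t))/2.
    """
    if rate < 0:
        raise DomainError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    states = {}
    root = tree.tree.seed_node
    states[root] = int(rng.integers(2))
    tip_states = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
            parent_state = states[node.parent_node]
            flip = rng.random() < p_flip
            states[node] = parent_state ^ int(flip)
        if node.is_leaf():
            tip_states[node.taxon.label] = states[node]
    return tip_states


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """A complete generated study with its generating parameters."""

    tree: CalibratedPhylogeny
    prey_tree: CalibratedPhylogeny
    diets: dict[str, DietProfile]
    traits: pd.DataFrame
    assays: pd.DataFrame
    yields: pd.DataFrame
    silk_states: dict[str, int]
    ground_truth: GroundTruth


def make_dataset(
    n_species: int = 75,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    n_assay_species: int = 64,
    n_yield_species: int = 47,
    n_yield_measures: int = 60,
) -> SyntheticDataset:
    """Generate a full study: tree, diets, traits, assays and yields.

    Diet data cover ``n_assay_species`` of the species (the remainder
    emulate species excluded for lacking diet data); yields cover a random
    ``n_yield_species`` subset with ``n_yield_measures`` total measures.
    """
    gt = ground_truth or GroundTruth(seed=seed)
    ss = np.random.SeedSequence(seed)
    # fixed spawn order: tree, silk, diets, traits, ld50, yield, subsets
    s_tree, s_silk, s_diet, s_trait, s_ld50, s_yield, s_sub = ss.spawn(7)

    tree = simulate_tree(n_species, s_tree)
    species = [t for t in tree.tip_labels]
    silk = simulate_binary_trait(tree, gt.mk_rate, s_silk)
    traits = simulate_traits(species, s_trait, silk_states=silk)

    sub_rng = np.random.default_rng(s_sub)
    assay_sp = sorted(
        species[int(i)] for i in sub_rng.choice(
            n_species, size=min(n_assay_species, n_species), replace=False
        )
    )
    diets = simulate_diets(assay_sp, seed=s_diet)
    prey_tree = prey_reference_tree()
    sim = simulate_ld50(tree, diets, traits, gt, s_ld50,
                        prey_tree=prey_tree)

    yield_sp = sorted(
        species[int(i)] for i in sub_rng.choice(
            n_species, size=min(n_yield_species, n_species), replace=False
        )
    )
    yields = simulate_yield(
        traits[traits["species"].isin(yield_sp)],
        exponent=gt.yield_exponent,
        noise_sd=gt.yield_noise_sd,
        seed=s_yield,
        intercept=gt.yield_intercept,
        n_measures=n_yield_measures,
    )
    return SyntheticDataset(
        tree=tree,
        prey_tree=prey_tree,
        diets=diets,
        traits=traits,
        assays=sim.table,
        yields=yields,
        silk_states=silk,
        ground_truth=gt,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write a dataset in the CSV/newick formats the readers accept."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        written.append(path)

    _write("tree.newick", ds.tree.to_newick() + "\n")
    _write("prey_tree.newick", ds.prey_tree.to_newick() + "\n")

    traits = ds.traits.copy()
    traits["silk_use"] = traits["silk_use"].map(
        {True: "true", False: "false"}
    )
    _write("traits.csv", traits.to_csv(index=False))

    diet_rows = []
    for sp, profile in ds.diets.items():
        for taxon, w in profile.weights.items():
            diet_rows.append({
                "species": sp, "prey_taxon": taxon, "rank": "class",
                "qual_label": "", "quant_proportion": repr(w),
            })
    _write("diet_reports.csv", pd.DataFrame(diet_rows).to_csv(index=False))

    cmap = pd.DataFrame(
        [{"prey_taxon": k, "class": v} for k, v in prey_class_map().items()]
    )
    _write("class_map.csv", cmap.to_csv(index=False))

    assays = ds.assays[[
        "species", "model_organism", "ld50_mg_per_kg", "route",
    ]].copy()
    assays["lyophilized"] = "true"
    _write("assays.csv", assays.to_csv(index=False))
    _write("assay_design.csv", ds.assays.to_csv(index=False))
    _write("yields.csv", ds.yields.to_csv(index=False))

    gt = asdict(ds.ground_truth)
    _write("ground_truth.json", json.dumps(gt, indent=2, sort_keys=True))
    return written
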