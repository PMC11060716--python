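"""Synthetic data generators for every stage of the pipeline.

These generators emulate the statistical structure the analyses assume —
Brownian-motion trait evolution with diet-group offsets on a birth-only
(Yule) tree, Dirichlet diet compositions per category, planar strain
fields with a controllable area-weighted mean and heterogeneity, and
circular-arc claw outlines — so every downstream stage is testable
without external downloads.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .fea import StrainField
from .io import DietComposition, TraitTable
from .trees import Phylogeny

__all__ = [
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_strain_field",
    "simulate_claw_arc",
    "simulate_diet_compositions",
]


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> Phylogeny:
    """Pure-birth ultrametric tree conditioned on ``n_tips`` extant tips.

    Lineages split at rate ``birth_rate`` per Ma per lineage.  The tree
    is grown until ``n_tips`` lineages exist and truncated at the moment
    the next (unrealised) speciation would occur, so terminal branches
    have positive length.  Tips are labelled ``t1 .. tn``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    # active lineages as (node, birth_time)
    t = 0.0
    active = [(root, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        node, birth = active.pop(i)
        node.edge.length = t - birth if node is not root else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.extend([(left, t), (right, t)])
    # time of the next would-be speciation defines the present
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for j, (node, birth) in enumerate(active):
        node.edge.length = t - birth
    for j, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_ns.new_taxon(label=f"t{j + 1}")
    if root.edge is not None:
        root.edge.length = None
    tree.is_rooted = True
    return Phylogeny(tree)


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2: float,
    root_state: float,
    group_map: dict | None = None,
    offsets: dict | None = None,
    seed: int = 0,
    trait_name: str = "trait",
    unit: str = "dimensionless",
) -> TraitTable:
    """Brownian-motion tip values plus a per-group mean shift.

    Each edge contributes an independent Normal(0, sigma2 * length)
    increment; the expected tip value is ``root_state`` plus the offset
    of its group.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    offsets = offsets or {}
    group_map = group_map or {}
    if offsets and group_map:
        missing = [t for t in tree.tip_labels if t not in group_map]
        if missing:
            raise ValueError(f"tips without group assignment: {missing}")
    rng = np.random.default_rng(seed)
    values: dict = {}
    states = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
        else:
            el = node.edge.length or 0.0
            states[node] = states[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * el)
            )
        if node.is_leaf():
            lab = node.taxon.label if node.taxon is not None else node.label
            shift = offsets.get(group_map.get(lab), 0.0) if offsets else 0.0
            values[lab] = states[node] + shift
    data = pd.DataFrame({trait_name: pd.Series(values)})
    data = data.loc[tree.tip_labels]
    data.index.name = "taxon"
    return TraitTable(data=data, units={trait_name: unit})


def simulate_strain_field(
    n_elements: int,
    target_mwam: float,
    heterogeneity: float = 0.0,
    seed: int = 0,
) -> StrainField:
    """Planar strain field with an exact area-weighted mean.

    ``heterogeneity`` in [0, 1] is the expected fraction of model area
    under extreme (high or low, far-from-mean) strain rather than
    intermediate strain: 0 gives a uniform field, 1 a fully two-mode
    field.  The field is rescaled after generation so the MWAM equals
    ``target_mwam`` to floating-point accuracy.
    """
    if target_mwam <= 0:
        raise ValueError("target_mwam must be positive")
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    area = rng.lognormal(mean=0.0, sigma=0.4, size=n_elements)
    if heterogeneity == 0.0:
        strain = np.full(n_elements, target_mwam)
    else:
        extreme = rng.random(n_elements) < heterogeneity
        sign = rng.integers(2, size=n_elements) * 2 - 1
        centre = np.where(extreme, 1.0 + 0.85 * sign, 1.0)
        strain = centre * (1.0 + 0.02 * rng.standard_normal(n_elements))
        strain = np.clip(strain, 1e-9, None)
        strain *= target_mwam / (np.sum(area * strain) / np.sum(area))
    return StrainField(element_id=np.arange(n_elements), area=area, strain=strain)


def simulate_claw_arc(
    subtended_angle: float,
    ungual_length: float,
    n_points: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Points on a circular arc with the given subtended angle (degrees).

    The chord from first to last point has length ``ungual_length``; the
    whole arc is given a random rigid rotation and translation (from
    ``seed``) so fitted angles must be pose-invariant.
    """
    if not 0 < subtended_angle < 180:
        raise ValueError("subtended_angle must be in (0, 180) degrees")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    theta = np.radians(subtended_angle)
    radius = ungual_length / (2.0 * np.sin(theta / 2.0))
    angles = np.linspace(-theta / 2.0, theta / 2.0, n_points)
    pts = np.column_stack([radius * np.sin(angles), radius * np.cos(angles)])
    rot_angle = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(rot_angle), np.sin(rot_angle)
    rot = np.array([[c, -s], [s, c]])
    return pts @ rot.T + rng.uniform(-10, 10, size=2)


#: Dirichlet concentration vectors putting ~80% of mass on the defining
#: food source of each category (order follows the EltonTraits fields).
DEFAULT_DIET_CONCENTRATIONS = {
    "Frugivore": {"Diet-Fruit": 40.0, "Diet-Inv": 2.0, "Diet-Seed": 2.0, "Diet-PlantO": 2.0},
    "Invertivore": {"Diet-Inv": 40.0, "Diet-Fruit": 2.0, "Diet-Seed": 2.0, "Diet-PlantO": 2.0},
    "Nectarivore": {"Diet-Nect": 40.0, "Diet-Inv": 3.0, "Diet-Fruit": 2.0},
    "Folivore": {"Diet-PlantO": 40.0, "Diet-Seed": 2.0, "Diet-Fruit": 2.0, "Diet-Inv": 2.0},
    "Generalist": {
        "Diet-Inv": 8.0, "Diet-Fruit": 8.0, "Diet-Seed": 8.0,
        "Diet-PlantO": 8.0, "Diet-Vfish": 8.0,
    },
}


def simulate_diet_compositions(
    n_per_class: int,
    concentrations: dict | None = None,
    seed: int = 0,
) -> tuple[list[DietComposition], list[str]]:
    """Class-conditional Dirichlet diet compositions summing to 100.

    Returns the composition list and the true class labels in step.
    """
    concentrations = concentrations or DEFAULT_DIET_CONCENTRATIONS
    rng = np.random.default_rng(seed)
    comps, labels = [], []
    for label, conc in concentrations.items():
        fields = list(conc)
        alpha = np.array([conc[f] for f in fields], dtype=float)
        draws = rng.dirichlet(alpha, size=n_per_class) * 100.0
        for row in draws:
            comps.append(DietComposition(percentages=dict(zip(fields, row))))
            labels.append(label)
    return comps, labels
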