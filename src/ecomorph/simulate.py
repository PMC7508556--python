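"""Synthetic study generation with the statistical structure the
analyses assume.

The generative model mirrors an island radiation: species means evolve
by Brownian motion on a pure-birth phylogeny, each ecomorph adds a
shared effect vector (common across islands), islands add a deviation
whose scale delta controls parallelism (delta=0 gives perfectly parallel
divergence in expectation), and individuals scatter iid around their
species mean. Landmark configurations are emitted by deforming a
template shape inside an orthonormal basis and applying nuisance
similarity transforms, so the Procrustes stage has real work to do. A
two-species rearing experiment injects treatment effects at an exact,
known angle to a supplied divergence vector. Every generator records its
ground truth so parameter recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import ECOMORPHS, ISLANDS
from .morphometry import N_LANDMARKS, LandmarkConfiguration, centroid_size, mirror_configuration

# trait-column naming ------------------------------------------------------

LENGTH_NAMES = (
    "len_humerus", "len_ulna", "len_femur", "len_tibia",
    "len_fore_phal1", "len_fore_phal2", "len_fore_phal3", "len_fore_phal4",
    "len_fore_phal5", "len_fore_claw",
    "len_hind_phal1", "len_hind_phal2", "len_hind_phal3", "len_hind_phal4",
    "len_hind_claw",
)
THICKNESS_NAMES = (
    "thick_humerus_diam", "thick_humerus_cort", "thick_ulna_diam", "thick_ulna_cort",
    "thick_femur_diam", "thick_femur_cort", "thick_tibia_diam", "thick_tibia_cort",
)
SIZE_NAME = "size_pelvic_cs"


def shape_columns(prefix: str) -> list[str]:
    return [f"{prefix}L{l + 1}_{ax}" for l in range(N_LANDMARKS) for ax in ("x", "y", "z")]


def trait_columns() -> list[str]:
    """The canonical 132 trait column names, in assembly order."""
    return (
        shape_columns("shape_pec_")
        + shape_columns("shape_pel_")
        + list(LENGTH_NAMES)
        + list(THICKNESS_NAMES)
        + [SIZE_NAME]
    )


# tree ---------------------------------------------------------------------


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` tips, scaled to unit height."""
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # active lineages as (node, birth_time)
    active = [(root.new_child(), 0.0), (root.new_child(), 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / len(active))
    labels = [f"sp{i + 1:03d}" for i in range(n_species)]
    rng.shuffle(labels)
    for (node, birth), label in zip(active, labels):
        node.edge.length = t_end - birth
        node.taxon = tns.require_taxon(label=label)
    if t_end > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= t_end
    return tree


def brownian_traits(tree: dendropy.Tree, n_traits: int, sigma2: float, rng: np.random.Generator) -> pd.DataFrame:
    """Species values from Brownian motion (rate sigma2 per unit height)."""
    values: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = values[id(parent)] if parent is not None else np.zeros(n_traits)
        step = 0.0 if node.edge.length in (None, 0) else rng.normal(
            0.0, np.sqrt(sigma2 * node.edge.length), n_traits
        )
        values[id(node)] = base + step
    rows = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    return pd.DataFrame.from_dict(rows, orient="index")


# radiation ----------------------------------------------------------------

#: ecomorphs absent per island; the two depauperate islands nest (the
#: trunk ecomorph genuinely occurs only on Cuba and Hispaniola), which is
#: what yields 53 usable quartets out of the 90 nominal combinations.
DEFAULT_ABSENCES = {"Jamaica": {"trunk"}, "PuertoRico": {"trunk", "crown-giant"}}


@dataclass
class RadiationParams:
    """Study-design and generative parameters of the simulated radiation.

    Defaults emulate the comparative design: 95 species over 4 islands x
    6 ecomorphs with 3 island-ecomorph absences, 1-14 individuals per
    species with mean about 2.7, and 132 traits (54+54 shape, 15 length,
    8 thickness, 1 size).
    """

    n_species: int = 95
    absences: dict = field(default_factory=lambda: {k: set(v) for k, v in DEFAULT_ABSENCES.items()})
    individuals_mean_extra: float = 1.73   # individuals ~ 1 + Poisson(mean_extra), capped at 14
    individuals_max: int = 14
    bm_sigma2: float = 1.0
    ecomorph_effect_sd: float = 1.5        # per-trait sd of the shared ecomorph effect vectors
    island_deviation_sd: float = 0.5       # delta: 0 means perfectly parallel divergence
    noise_sd: float = 1.0
    missing_rate: float = 0.0053
    seed: int = 0

    def presence(self) -> list[tuple[str, str]]:
        cells = []
        for island in ISLANDS:
            absent = self.absences.get(island, set())
            for eco in ECOMORPHS:
                if eco not in absent:
                    cells.append((island, eco))
        per_island = {i: sum(1 for isl, _ in cells if isl == i) for i in ISLANDS}
        # islands removed wholesale are fine; a represented island needs >= 2 ecomorphs
        if any(v == 1 for v in per_island.values()):
            raise ValueError("every represented island needs at least two ecomorphs")
        if not cells:
            raise ValueError("presence matrix is empty")
        return cells


@dataclass
class SimulatedRadiation:
    tree: dendropy.Tree
    metadata: pd.DataFrame            # specimen_id-indexed
    traits: pd.DataFrame              # raw (latent) scale, 132 columns
    truth: dict


def simulate_radiation(tree: dendropy.Tree, params: RadiationParams) -> SimulatedRadiation:
    """Individual trait rows for a radiation with known ground truth.

    Species mean = BM(tree) + beta(ecomorph) + delta * dev(island,
    ecomorph); individual = species mean + iid noise. With delta=0 the
    true island trajectories for any ecomorph pair are exactly parallel
    in expectation. The returned truth dict carries the species means
    and both effect-vector families.
    """
    rng = np.random.default_rng(params.seed)
    cols = trait_columns()
    m = len(cols)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(species) != params.n_species:
        params = RadiationParams(**{**params.__dict__, "n_species": len(species)})
    cells = params.presence()

    order = list(species)
    rng.shuffle(order)
    assignment = {sp: cells[i % len(cells)] for i, sp in enumerate(order)}

    bm = brownian_traits(tree, m, params.bm_sigma2, rng)
    bm.columns = cols
    beta = {eco: rng.normal(0.0, params.ecomorph_effect_sd, m) for eco in ECOMORPHS}
    dev = {cell: rng.normal(0.0, 1.0, m) for cell in cells}

    species_means = {}
    for sp in species:
        island, eco = assignment[sp]
        species_means[sp] = (
            bm.loc[sp].to_numpy()
            + beta[eco]
            + params.island_deviation_sd * dev[(island, eco)]
        )

    rows, meta_rows, ids = [], [], []
    counter = 0
    for sp in species:
        island, eco = assignment[sp]
        k = min(1 + rng.poisson(params.individuals_mean_extra), params.individuals_max)
        for _ in range(k):
            counter += 1
            sid = f"spec{counter:04d}"
            ids.append(sid)
            rows.append(species_means[sp] + rng.normal(0.0, params.noise_sd, m))
            meta_rows.append(
                {"specimen_id": sid, "species": sp, "island": island, "ecomorph": eco,
                 "sex": "male", "source": "museum", "treatment": None}
            )
    traits = pd.DataFrame(rows, index=ids, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("specimen_id")
    truth = {
        "assignment": assignment,
        "species_means": pd.DataFrame.from_dict(species_means, orient="index", columns=cols),
        "ecomorph_effects": beta,
        "island_deviations": dev,
        "params": params,
    }
    return SimulatedRadiation(tree=tree, metadata=metadata, traits=traits, truth=truth)


def true_trajectory(truth: dict, e1: str, e2: str, island: str) -> np.ndarray:
    """Ground-truth divergence vector for an ecomorph pair on one island."""
    p: RadiationParams = truth["params"]
    beta = truth["ecomorph_effects"]
    dev = truth["island_deviations"]
    d = beta[e1] - beta[e2]
    if (island, e1) in dev:
        d = d + p.island_deviation_sd * dev[(island, e1)]
    if (island, e2) in dev:
        d = d - p.island_deviation_sd * dev[(island, e2)]
    return d


# landmarks ----------------------------------------------------------------


@dataclass
class TemplateShape:
    """A template landmark configuration plus an orthonormal deformation basis."""

    structure: str
    template: np.ndarray           # 18 x 3, mm
    basis: np.ndarray              # 54 x k, orthonormal columns

    def __post_init__(self):
        self.template = np.asarray(self.template, float)
        self.basis = np.asarray(self.basis, float)
        if self.template.shape != (N_LANDMARKS, 3):
            raise ValueError("template must be 18 x 3")
        if centroid_size(self.template) <= 1e-9:
            raise ValueError("degenerate template")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("deformation basis must be orthonormal")


def make_template(structure: str, k: int = 8, seed: int = 0) -> TemplateShape:
    """A reproducible non-degenerate template with a random orthonormal basis."""
    rng = np.random.default_rng(seed)
    template = rng.normal(0.0, 1.0, (N_LANDMARKS, 3))
    template -= template.mean(axis=0)
    template /= centroid_size(template)          # unit-size template; scale applied per specimen
    q, _ = np.linalg.qr(rng.normal(size=(3 * N_LANDMARKS, k)))
    return TemplateShape(structure=structure, template=template, basis=q)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, -1] *= -1
    return q


def simulate_landmarks(
    template: TemplateShape,
    coefficients: np.ndarray,
    specimen_ids,
    scales=None,
    noise_sd: float = 0.0,
    right_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, LandmarkConfiguration]:
    """Raw landmark configurations deformed from a template.

    Each specimen's shape is template + basis @ coefficients + iid
    landmark noise, then hit with a random rotation, translation, and
    its scale; a ``right_fraction`` of configurations is emitted as
    right-side (mirrored) to exercise the mirroring step.
    """
    rng = np.random.default_rng(seed)
    coefficients = np.atleast_2d(np.asarray(coefficients, float))
    n = coefficients.shape[0]
    if coefficients.shape[1] != template.basis.shape[1]:
        raise ValueError("coefficient dimension does not match deformation basis")
    if scales is None:
        scales = np.ones(n)
    scales = np.asarray(scales, float)
    out = {}
    for i, sid in enumerate(specimen_ids):
        shape = template.template + (template.basis @ coefficients[i]).reshape(N_LANDMARKS, 3)
        if noise_sd > 0:
            shape = shape + rng.normal(0.0, noise_sd, shape.shape)
        shape = scales[i] * (shape @ _random_rotation(rng).T) + rng.normal(0.0, 5.0, 3)
        cfg = LandmarkConfiguration(structure=template.structure, side="left", coords=shape)
        if rng.random() < right_fraction:
            cfg = mirror_configuration(cfg)      # emit as right-side raw data
        out[str(sid)] = cfg
    return out


# plasticity experiment ----------------------------------------------------


@dataclass
class PlasticityParams:
    """Design of the two-species, two-treatment rearing experiment.

    Default per-treatment sample sizes follow the emulated experiment
    (41/34 males for the runner species, 22/23 for the climber). The
    treatment effect vector is constructed at exactly ``target_angle``
    degrees to the supplied divergence vector, with trait-space norm
    ``effect_magnitude`` (in units of the individual noise sd).
    """

    species: tuple[str, str] = ("sagrei", "carolinensis")
    n_per_treatment: dict = field(
        default_factory=lambda: {"sagrei": (41, 34), "carolinensis": (22, 23)}
    )
    target_angle: dict = field(default_factory=lambda: {"sagrei": 90.0, "carolinensis": 90.0})
    effect_magnitude: float = 30.0
    noise_sd: float = 1.0
    seed: int = 0


def effect_at_angle(divergence: np.ndarray, angle_deg: float, magnitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """A vector at an exact angle to ``divergence`` (Gram-Schmidt mixing)."""
    u = np.asarray(divergence, float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("divergence vector must be non-zero")
    if magnitude <= 0:
        raise ValueError("effect magnitude must be positive for a defined target angle")
    u = u / nu
    v = rng.normal(size=u.shape)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    rad = np.radians(angle_deg)
    return magnitude * (np.cos(rad) * u + np.sin(rad) * v)


def simulate_plasticity_experiment(
    params: PlasticityParams, divergence_vector: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Experimental trait rows with treatment effects at known angles.

    Returns (metadata, traits, truth); traits are on the same raw scale
    as the radiation generator. The broad-treatment group carries the
    effect, so the (broad - narrow) trajectory points along it.
    """
    rng = np.random.default_rng(params.seed)
    divergence = np.asarray(divergence_vector, float)
    m = divergence.shape[0]
    cols = trait_columns()
    if m != len(cols):
        cols = [f"trait_{i + 1}" for i in range(m)]
    rows, meta_rows, ids = [], [], []
    effects = {}
    counter = 0
    for sp in params.species:
        angle = params.target_angle[sp]
        effect = effect_at_angle(divergence, angle, params.effect_magnitude, rng)
        effects[sp] = effect
        base = rng.normal(0.0, 1.0, m)
        for treatment, n in zip(("broad", "narrow"), params.n_per_treatment[sp]):
            shift = effect if treatment == "broad" else 0.0
            for _ in range(n):
                counter += 1
                sid = f"exp{counter:04d}"
                ids.append(sid)
                rows.append(base + shift + rng.normal(0.0, params.noise_sd, m))
                meta_rows.append(
                    {"specimen_id": sid, "species": sp, "island": None, "ecomorph": None,
                     "sex": "male", "source": "experiment", "treatment": treatment}
                )
    traits = pd.DataFrame(rows, index=ids, columns=cols)
    metadata = pd.DataFrame(meta_rows).set_index("specimen_id")
    truth = {"effects": effects, "divergence": divergence, "params": params}
    return metadata, traits, truth


# missing data -------------------------------------------------------------


def inject_missing(table: pd.DataFrame, rate: float, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delete cells uniformly at random; returns (table, boolean mask)."""
    if not (0.0 <= rate < 0.5):
        raise ValueError("missing rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(
        rng.random(table.shape) < rate, index=table.index, columns=table.columns
    )
    out = table.mask(mask)
    return out, mask


# full study ---------------------------------------------------------------

#: raw linear baselines in mm (lengths then thicknesses), per unit body scale
_BASE_MM = np.array(
    [12.0, 10.0, 14.0, 12.5, 3.0, 2.6, 2.2, 1.8, 1.2, 0.8, 3.2, 2.7, 2.1, 1.4, 0.9,
     1.30, 0.45, 1.10, 0.40, 1.50, 0.55, 1.35, 0.50]
)


@dataclass
class SimulatedStudy:
    tree: dendropy.Tree
    metadata: pd.DataFrame
    latent: pd.DataFrame                  # generative 132-trait rows (ground truth scale)
    landmarks: dict                       # specimen -> {structure: LandmarkConfiguration}
    linear: pd.DataFrame                  # raw mm, with injected missing cells
    linear_mask: pd.DataFrame
    truth: dict


def simulate_study(
    params: RadiationParams | None = None,
    deform_scale: float = 0.03,
    landmark_noise_sd: float = 0.002,
    right_fraction: float = 0.05,
    n_deform: int = 8,
    seed: int | None = None,
) -> SimulatedStudy:
    """Generate a complete raw study: tree, landmarks, linear table.

    The radiation's latent shape-block values drive template deformations
    (scaled into the small-deformation regime); latent length/thickness
    values modulate positive raw measurements around realistic baselines;
    a per-specimen body scale (lognormal around 20 mm centroid size,
    driven by the latent size trait) multiplies both the landmarks and
    the raw linear measurements, so size correction has real work to do.
    """
    if params is None:
        params = RadiationParams()
    if seed is not None:
        params = RadiationParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(params.seed + 1)
    tree = simulate_tree(params.n_species, seed=params.seed)
    rad = simulate_radiation(tree, params)
    n = rad.traits.shape[0]
    ids = list(rad.traits.index)

    body_scale = 20.0 * np.exp(0.08 * rad.traits[SIZE_NAME].to_numpy())

    landmarks: dict = {sid: {} for sid in ids}
    templates = {}
    for structure, prefix in (("pectoral", "shape_pec_"), ("pelvic", "shape_pel_")):
        template = make_template(
            structure, k=n_deform, seed=params.seed + zlib.crc32(structure.encode()) % 1000
        )
        templates[structure] = template
        coeffs = deform_scale * rad.traits[shape_columns(prefix)[:n_deform]].to_numpy()
        cfgs = simulate_landmarks(
            template, coeffs, ids,
            scales=body_scale * (0.8 if structure == "pectoral" else 1.0),
            noise_sd=landmark_noise_sd, right_fraction=right_fraction,
            seed=params.seed + 2 + (structure == "pelvic"),
        )
        for sid, cfg in cfgs.items():
            landmarks[sid][structure] = cfg

    lin_cols = list(LENGTH_NAMES) + list(THICKNESS_NAMES)
    latent_lin = rad.traits[lin_cols].to_numpy()
    modulation = np.exp(0.04 * latent_lin)       # strictly positive, monotone in the latent value
    linear = pd.DataFrame(
        _BASE_MM[None, :] * modulation * body_scale[:, None] / 20.0,
        index=ids, columns=lin_cols,
    )
    linear, mask = inject_missing(linear, params.missing_rate, seed=params.seed + 5)

    truth = dict(rad.truth)
    truth.update({"templates": templates, "deform_scale": deform_scale, "body_scale": body_scale})
    return SimulatedStudy(
        tree=tree, metadata=rad.metadata, latent=rad.traits, landmarks=landmarks,
        linear=linear, linear_mask=mask, truth=truth,
    )
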