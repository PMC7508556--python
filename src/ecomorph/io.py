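"""Data model, file readers/writers, and phylogeny handling.

Specimen/trait tables are delimited text (comma default, tab accepted)
with fixed-named metadata columns followed by trait columns whose class
is encoded by prefix (``shape_pec_``, ``shape_pel_``, ``len_``,
``thick_``, ``size_``). Landmarks are long-format delimited text. Trees
are Newick, handled through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .morphometry import N_LANDMARKS, LandmarkConfiguration, classify_columns

ISLANDS = ("Cuba", "Hispaniola", "Jamaica", "PuertoRico")
ECOMORPHS = ("trunk-ground", "trunk-crown", "crown-giant", "twig", "grass-bush", "trunk")
SEXES = ("male", "female", "unknown")
SOURCES = ("museum", "experiment")
TREATMENTS = ("broad", "narrow")

METADATA_COLUMNS = ("specimen_id", "species", "island", "ecomorph", "sex", "source", "treatment")
NA_VALUES = ("", "NA")


@dataclass
class SpecimenRecord:
    """Metadata for one museum or lab-reared specimen."""

    specimen_id: str
    species: str
    island: str | None
    ecomorph: str | None
    sex: str
    source: str
    treatment: str | None

    def __post_init__(self):
        if self.island is not None and self.island not in ISLANDS:
            raise ValueError(f"{self.specimen_id}: unknown island {self.island!r}")
        if self.ecomorph is not None and self.ecomorph not in ECOMORPHS:
            raise ValueError(f"{self.specimen_id}: unknown ecomorph {self.ecomorph!r}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.specimen_id}: unknown sex {self.sex!r}")
        if self.source not in SOURCES:
            raise ValueError(f"{self.specimen_id}: unknown source {self.source!r}")
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ValueError(f"{self.specimen_id}: unknown treatment {self.treatment!r}")
        if self.source == "experiment" and self.treatment is None:
            raise ValueError(f"{self.specimen_id}: experimental specimen lacks a treatment")
        if self.source == "museum" and self.treatment is not None:
            raise ValueError(f"{self.specimen_id}: museum specimen cannot carry a treatment")


@dataclass
class MorphDataset:
    """Specimen records plus their trait rows, and optionally raw inputs."""

    records: list[SpecimenRecord]
    traits: pd.DataFrame                       # specimen_id-indexed trait columns
    landmarks: dict | None = None              # specimen_id -> {structure: LandmarkConfiguration}
    linear: pd.DataFrame | None = None         # raw lengths/thicknesses in mm

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "island": r.island,
                "ecomorph": r.ecomorph,
                "sex": r.sex,
                "source": r.source,
                "treatment": r.treatment,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows).set_index("specimen_id")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(ds: MorphDataset) -> ValidationReport:
    """Check dataset-level invariants and tally specimens per island/ecomorph."""
    report = ValidationReport()
    ids = [r.specimen_id for r in ds.records]
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        report.errors.append(f"duplicate specimen ids: {dupes}")
    missing_rows = set(ids) ^ set(ds.traits.index)
    if missing_rows:
        report.errors.append(f"records and trait rows mismatch: {sorted(missing_rows)}")
    if ds.linear is not None:
        vals = ds.linear.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            report.errors.append("raw linear measurements must be strictly positive")
    meta = ds.metadata
    report.counts = (
        meta.dropna(subset=["island", "ecomorph"])
        .groupby(["island", "ecomorph"], observed=True)
        .size()
        .to_dict()
    )
    return report


# ---------------------------------------------------------------------------
# specimen tables


def _sep_for(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_specimen_table(path) -> MorphDataset:
    """Read a delimited specimen/trait table.

    Metadata columns come first (fixed names), every remaining column is
    a trait. Missing values may be empty cells or "NA". Duplicate ids,
    unknown category labels and non-numeric trait cells are load errors
    naming the offending row/column.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, keep_default_na=False, na_values=list(NA_VALUES)
    )
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing metadata columns {missing_cols}")

    ids = df["specimen_id"]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate specimen ids {dupes}")

    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                species=row["species"],
                island=None if pd.isna(row["island"]) else row["island"],
                ecomorph=None if pd.isna(row["ecomorph"]) else row["ecomorph"],
                sex="unknown" if pd.isna(row["sex"]) else row["sex"],
                source=row["source"],
                treatment=None if pd.isna(row["treatment"]) else row["treatment"],
            )
        )

    trait_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    traits = df[trait_cols].copy()
    for col in trait_cols:
        try:
            traits[col] = pd.to_numeric(traits[col])
        except (ValueError, TypeError) as exc:
            bad = traits[col][pd.to_numeric(traits[col], errors="coerce").isna() & traits[col].notna()]
            row_id = ids.iloc[bad.index[0]] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row_id!r}") from exc
    traits.index = ids.tolist()
    if trait_cols:
        classify_columns(trait_cols)  # raises on unclassifiable names
    return MorphDataset(records=records, traits=traits)


def write_specimen_table(ds: MorphDataset, path, sep: str = ",") -> None:
    meta = ds.metadata.reset_index()
    traits = ds.traits.reset_index(drop=True)
    pd.concat([meta, traits], axis=1).to_csv(path, sep=sep, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# landmarks

LANDMARK_COLUMNS = ("specimen_id", "structure", "side", "landmark", "x", "y", "z")


def read_landmarks(path) -> dict[str, dict[str, LandmarkConfiguration]]:
    """Read a long-format landmark file into per-specimen configurations.

    Rows carry (specimen_id, structure, side, landmark index 1-18,
    x, y, z) in mm; each (specimen, structure) must contribute exactly
    18 indices.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark columns {missing}")
    out: dict[str, dict[str, LandmarkConfiguration]] = {}
    for (sid, structure), grp in df.groupby(["specimen_id", "structure"], sort=True):
        idx = grp["landmark"].astype(int).to_numpy()
        if sorted(idx) != list(range(1, N_LANDMARKS + 1)):
            raise ValueError(
                f"{path}: expected {N_LANDMARKS} landmarks (1..{N_LANDMARKS}) for "
                f"specimen {sid!r} structure {structure!r}, got {len(idx)}"
            )
        sides = grp["side"].unique()
        if len(sides) != 1:
            raise ValueError(f"{path}: mixed sides for specimen {sid!r} structure {structure!r}")
        grp = grp.sort_values("landmark")
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        out.setdefault(str(sid), {})[structure] = LandmarkConfiguration(
            structure=structure, side=sides[0], coords=coords
        )
    return out


def write_landmarks(landmarks: dict[str, dict[str, LandmarkConfiguration]], path, sep: str = ",") -> None:
    rows = []
    for sid in sorted(landmarks):
        for structure in sorted(landmarks[sid]):
            cfg = landmarks[sid][structure]
            for i, (x, y, z) in enumerate(cfg.coords, start=1):
                rows.append((sid, structure, cfg.side, i, x, y, z))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# phylogeny


def read_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Accepts a path or a Newick string. Edges without lengths (other than
    the root edge) are an error; zero-length edges are tolerated with a
    warning downstream.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(source), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths along the path between two tips."""
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    if ta is None or tb is None:
        missing = [x for x, t in ((a, ta), (b, tb)) if t is None]
        raise ValueError(f"tips not found: {missing}")
    return float(pdm.patristic_distance(ta, tb))


def patristic_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    tx = []
    missing = []
    for label in taxa:
        t = tree.taxon_namespace.get_taxon(label)
        (missing if t is None else tx).append(label if t is None else t)
    if missing:
        raise ValueError(f"tips not found: {missing}")
    n = len(tx)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(tx[i], tx[j])
    return out


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Return a copy retaining only the requested tips.

    Redundant internal nodes are collapsed; patristic distances among
    retained tips are preserved exactly.
    """
    taxa = list(taxa)
    present = set(tip_labels(tree))
    missing = sorted(set(taxa) - present)
    if missing:
        raise ValueError(f"tips not found: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(taxa)
    return pruned


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = _root_tip_depths(tree)
    return bool(np.ptp(list(depths.values())) <= tol)


def _root_tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def graft_tip(tree: dendropy.Tree, new_tip: str, sister_tip: str, fraction: float = 0.5) -> dendropy.Tree:
    """Attach a new tip along a sister tip's terminal branch.

    The sister's terminal branch (length b) is split at ``fraction`` from
    its parent; the new tip's branch length is (1 - fraction) * b, so on
    an ultrametric tree the new tip is contemporaneous with its sister.
    Mirrors the tip-binding approach used to place recently split species
    whose phylogenetic affinity, but not divergence time, is known.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    labels = set(tip_labels(tree))
    if new_tip in labels:
        raise ValueError(f"tip {new_tip!r} already present")
    if sister_tip not in labels:
        raise ValueError(f"sister tip {sister_tip!r} not found")

    out = tree.clone(depth=1)
    sister = next(l for l in out.leaf_node_iter() if l.taxon.label == sister_tip)
    b = sister.edge.length
    if b is None or b <= 0:
        raise ValueError(f"sister tip {sister_tip!r} has a non-positive terminal branch")
    parent = sister.parent_node
    parent.remove_child(sister)
    joint = parent.new_child(edge_length=fraction * b)
    sister.edge.length = (1.0 - fraction) * b
    joint.add_child(sister)
    taxon = out.taxon_namespace.require_taxon(label=new_tip)
    joint.new_child(taxon=taxon, edge_length=(1.0 - fraction) * b)
    return out


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
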