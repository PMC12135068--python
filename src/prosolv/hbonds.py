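"""Geometric hydrogen-bond analysis: detection, category census, bridging
waters and per-residue contacts.

The default criterion is the GROMACS ``hbond`` geometry: donor-acceptor
distance <= 0.35 nm and H-D-A angle <= 30 degrees; both the values and the
angle convention (H-D-A vs D-H-A) are configurable.  All distances use the
minimal-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .md_io import Box, Frame, Topology, Trajectory, minimal_image

CATEGORIES = ("pp_inter", "pp_intra", "pw", "ww", "pd", "dd", "dw", "other")


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    With the ``hda`` convention a bond requires angle(H-D-A) <= angle_cutoff
    (default 30 deg); with ``dha`` it requires angle(D-H-A) >= angle_cutoff
    (a typical choice is 150 deg).
    """

    distance_cutoff: float = 0.35
    angle_cutoff: float = 30.0
    convention: str = "hda"

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")
        if self.convention not in ("hda", "dha"):
            raise ValueError("convention must be 'hda' or 'dha'")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    frame_index: int = 0


def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def find_hbonds(frame: Frame, topology: Topology,
                criterion: HBondCriterion | None = None) -> list[HBond]:
    """All donor-hydrogen-acceptor triples satisfying the criterion.

    Requires donor/acceptor annotations on the topology.  The acceptor may
    be in the donor's molecule (intra-molecular bonds are real) but never
    the donor atom itself.  Output is sorted by (donor, acceptor, hydrogen).
    """
    crit = criterion or HBondCriterion()
    if len(topology.donors) == 0 and len(topology.acceptors) == 0:
        missing = np.unique(topology.resnames)
        raise ValueError(
            "topology carries no donor/acceptor annotations "
            f"(residues: {', '.join(map(str, missing[:8]))})")
    pos = frame.positions
    box = frame.box
    acceptors = topology.acceptors
    if len(acceptors) == 0 or len(topology.donors) == 0:
        return []
    wrapped_acc = np.mod(pos[acceptors], box.lengths) if box.periodic else pos[acceptors]
    tree = cKDTree(wrapped_acc, boxsize=box.lengths if box.periodic else None)
    d_atoms = topology.donors[:, 0]
    h_atoms = topology.donors[:, 1]
    wrapped_d = np.mod(pos[d_atoms], box.lengths) if box.periodic else pos[d_atoms]
    neighbour_lists = tree.query_ball_point(wrapped_d, crit.distance_cutoff)
    bonds: list[HBond] = []
    for k, neigh in enumerate(neighbour_lists):
        if not neigh:
            continue
        d, h = int(d_atoms[k]), int(h_atoms[k])
        acc = acceptors[np.asarray(neigh, dtype=int)]
        acc = acc[acc != d]
        if len(acc) == 0:
            continue
        da = minimal_image(pos[d], pos[acc], box)
        dist = np.linalg.norm(da, axis=-1)
        keep = dist <= crit.distance_cutoff
        acc, da, dist = acc[keep], da[keep], dist[keep]
        if len(acc) == 0:
            continue
        if crit.convention == "hda":
            dh = minimal_image(pos[d], pos[h], box)
            ang = _angles_deg(np.broadcast_to(dh, da.shape), da)
            ok = ang <= crit.angle_cutoff
        else:
            hd = minimal_image(pos[h], pos[d], box)
            ha = minimal_image(pos[h], pos[acc], box)
            ang = _angles_deg(np.broadcast_to(hd, ha.shape), ha)
            ok = ang >= crit.angle_cutoff
        for a, r, th in zip(acc[ok], dist[ok], ang[ok]):
            bonds.append(HBond(d, h, int(a), float(r), float(th)))
    bonds.sort(key=lambda b: (b.donor, b.acceptor, b.hydrogen))
    return bonds


def find_hbonds_brute(frame: Frame, topology: Topology,
                      criterion: HBondCriterion | None = None) -> list[HBond]:
    """O(n_donors * n_acceptors) reference detector (no spatial index)."""
    crit = criterion or HBondCriterion()
    pos = frame.positions
    box = frame.box
    bonds = []
    for d, h in topology.donors:
        for a in topology.acceptors:
            if a == d:
                continue
            da = minimal_image(pos[d], pos[a], box)
            dist = float(np.linalg.norm(da))
            if dist > crit.distance_cutoff:
                continue
            if crit.convention == "hda":
                dh = minimal_image(pos[d], pos[h], box)
                ang = float(_angles_deg(dh, da))
                if ang > crit.angle_cutoff:
                    continue
            else:
                hd = minimal_image(pos[h], pos[d], box)
                ha = minimal_image(pos[h], pos[a], box)
                ang = float(_angles_deg(hd, ha))
                if ang < crit.angle_cutoff:
                    continue
            bonds.append(HBond(int(d), int(h), int(a), dist, ang))
    bonds.sort(key=lambda b: (b.donor, b.acceptor, b.hydrogen))
    return bonds


# ---------------------------------------------------------------------------
# category census
# ---------------------------------------------------------------------------

def categorize(bond: HBond, topology: Topology) -> str:
    """Assign a bond to exactly one category from the molecule classes."""
    cd = topology.molecule_classes[bond.donor]
    ca = topology.molecule_classes[bond.acceptor]
    if "" in (cd, ca):
        raise ValueError("bond spans unclassified molecules")
    pair = frozenset((cd, ca))
    if pair == {"protein"}:
        same = (topology.molecule_ids[bond.donor]
                == topology.molecule_ids[bond.acceptor])
        return "pp_intra" if same else "pp_inter"
    if pair == {"protein", "water"}:
        return "pw"
    if pair == {"water"}:
        return "ww"
    if pair == {"protein", "disaccharide"}:
        return "pd"
    if pair == {"disaccharide"}:
        return "dd"
    if pair == {"disaccharide", "water"}:
        return "dw"
    return "other"


@dataclass
class HBondCensus:
    """Per-frame hydrogen-bond category counts with summary statistics."""

    counts: pd.DataFrame            # frames x CATEGORIES
    pp_intra_per_chain: pd.DataFrame
    n_waters: int = 0

    @property
    def mean(self) -> pd.Series:
        return self.counts.mean(axis=0)

    @property
    def std(self) -> pd.Series:
        return self.counts.std(axis=0, ddof=0)

    @property
    def stderr(self) -> pd.Series:
        return self.std / np.sqrt(len(self.counts))

    def per_water(self) -> pd.Series:
        """Means of the water-involving categories per water molecule."""
        if self.n_waters == 0:
            raise ValueError("census has no waters")
        return self.mean[["pw", "ww", "dw"]] / self.n_waters

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std,
                             "stderr": self.stderr})


def census(bonds_per_frame: Sequence[Sequence[HBond]],
           topology: Topology) -> HBondCensus:
    """Count bonds per category per frame; categories partition the bonds."""
    chain_mols = sorted(np.unique(
        topology.molecule_ids[topology.molecule_classes == "protein"]))
    rows, chain_rows = [], []
    for bonds in bonds_per_frame:
        row = dict.fromkeys(CATEGORIES, 0)
        crow = dict.fromkeys(chain_mols, 0)
        for b in bonds:
            cat = categorize(b, topology)
            row[cat] += 1
            if cat == "pp_intra":
                crow[int(topology.molecule_ids[b.donor])] += 1
        rows.append(row)
        chain_rows.append(crow)
    return HBondCensus(
        counts=pd.DataFrame(rows, columns=list(CATEGORIES)),
        pp_intra_per_chain=pd.DataFrame(chain_rows, columns=chain_mols),
        n_waters=topology.molecule_count("water"))


def census_trajectory(trajectory: Trajectory,
                      criterion: HBondCriterion | None = None) -> HBondCensus:
    bonds = [find_hbonds(f, trajectory.topology, criterion) for f in trajectory]
    return census(bonds, trajectory.topology)


# ---------------------------------------------------------------------------
# bridging waters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BridgingResult:
    """The three bridging estimates, all per protein molecule.

    ``eq1_literal`` evaluates the published group-count formula exactly as
    printed, (1/n) * (sum_i HB(p_i u w) + sum_i HB(p_i)) - HB(w-w), which
    algebraically reduces to 2*mean HB(p_i) + mean HB(p_i-w).
    ``eq1_difference_variant`` flips the inner sign and reduces to
    mean HB(p_i-w).  ``direct_count`` enumerates water (or ion) molecules
    hydrogen-bonded to >=2 distinct residues of one chain.  The three do
    not in general agree; all are reported.
    """

    eq1_literal: float
    eq1_difference_variant: float
    direct_count: float
    n_proteins: int


def bridging_direct(bonds: Iterable[HBond], topology: Topology,
                    include_ions: bool = True) -> dict:
    """Count bridging solvent molecules per protein chain.

    A water (or, with ``include_ions``, ion) molecule bridges a chain when
    it is hydrogen-bonded to two *distinct residues* of that chain; each
    molecule is counted once per chain it bridges.
    """
    solvent_classes = {"water"} | ({"cation", "anion"} if include_ions else set())
    partners: dict[int, set] = {}
    for b in bonds:
        for solv_atom, prot_atom in ((b.donor, b.acceptor), (b.acceptor, b.donor)):
            if (topology.molecule_classes[solv_atom] in solvent_classes
                    and topology.molecule_classes[prot_atom] == "protein"):
                mol = int(topology.molecule_ids[solv_atom])
                partners.setdefault(mol, set()).add(
                    (int(topology.molecule_ids[prot_atom]),
                     int(topology.resindices[prot_atom])))
    chains = sorted(np.unique(
        topology.molecule_ids[topology.molecule_classes == "protein"]))
    per_chain = dict.fromkeys((int(c) for c in chains), 0)
    for mol, prt in partners.items():
        for chain in {c for c, _ in prt}:
            if sum(1 for c, _ in prt if c == chain) >= 2:
                per_chain[chain] += 1
    total = sum(per_chain.values())
    return {"per_chain": per_chain, "total": total,
            "per_protein": total / max(len(chains), 1)}


def eq1_group_counts(bonds: Iterable[HBond], topology: Topology,
                     include_ions: bool = True) -> dict:
    """Group-internal bond counts feeding the bridging formula.

    For each chain i: ``union_i`` = bonds internal to (chain i + water
    [+ ions]) and ``protein_i`` = bonds internal to chain i alone;
    ``ww`` = bonds internal to the water[+ion] group.
    """
    solvent_classes = {"water"} | ({"cation", "anion"} if include_ions else set())
    chains = sorted(np.unique(
        topology.molecule_ids[topology.molecule_classes == "protein"]))
    cls = topology.molecule_classes
    mid = topology.molecule_ids
    union = dict.fromkeys((int(c) for c in chains), 0)
    protein = dict.fromkeys((int(c) for c in chains), 0)
    ww = 0
    for b in bonds:
        cd, ca = cls[b.donor], cls[b.acceptor]
        md, ma = int(mid[b.donor]), int(mid[b.acceptor])
        d_solv, a_solv = cd in solvent_classes, ca in solvent_classes
        if d_solv and a_solv:
            ww += 1
            for c in union:
                union[c] += 1
        elif cd == "protein" and ca == "protein":
            if md == ma:
                protein[md] += 1
                union[md] += 1
        elif d_solv and ca == "protein":
            union[ma] += 1
        elif a_solv and cd == "protein":
            union[md] += 1
    return {"union": union, "protein": protein, "ww": ww}


def bridging_eq1(group_counts: dict, n_proteins: int | None = None) -> tuple[float, float]:
    """Evaluate the group-count bridging formula (literal and sign variant).

    literal  = (1/n) (sum_i union_i + sum_i protein_i) - ww
    variant  = (1/n) (sum_i union_i - sum_i protein_i) - ww
    """
    union = group_counts["union"]
    protein = group_counts["protein"]
    ww = group_counts["ww"]
    n = n_proteins or len(union)
    if n == 0:
        raise ValueError("no protein chains")
    s_u = sum(union.values())
    s_p = sum(protein.values())
    literal = (s_u + s_p) / n - ww
    variant = (s_u - s_p) / n - ww
    return literal, variant


def bridging_analysis(frame: Frame, topology: Topology,
                      criterion: HBondCriterion | None = None,
                      include_ions: bool = True) -> BridgingResult:
    """All three bridging estimates for one frame."""
    bonds = find_hbonds(frame, topology, criterion)
    gc = eq1_group_counts(bonds, topology, include_ions)
    literal, variant = bridging_eq1(gc)
    direct = bridging_direct(bonds, topology, include_ions)
    return BridgingResult(eq1_literal=literal,
                          eq1_difference_variant=variant,
                          direct_count=direct["per_protein"],
                          n_proteins=len(gc["union"]))


# ---------------------------------------------------------------------------
# residue contacts
# ---------------------------------------------------------------------------

def contacts_per_residue(frame: Frame, topology: Topology,
                         cutoff: float = 0.6,
                         exclude_neighbours: int = 1) -> pd.Series:
    """Number of partner residues per protein residue.

    A contact is any heavy-atom pair of two residues within ``cutoff`` nm
    (minimal image); sequence neighbours with |delta residue| <=
    ``exclude_neighbours`` on the same chain are excluded.  Inter-chain
    contacts always count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.array([i for i in topology.heavy_atoms()
                      if topology.molecule_classes[i] == "protein"])
    residues = np.unique(topology.resindices[heavy]) if len(heavy) else np.array([], int)
    partners: dict[int, set] = {int(r): set() for r in residues}
    if len(heavy) == 0:
        return pd.Series(dtype=float)
    box = frame.box
    pos = frame.positions[heavy]
    wrapped = np.mod(pos, box.lengths) if box.periodic else pos
    tree = cKDTree(wrapped, boxsize=box.lengths if box.periodic else None)
    for i, j in tree.query_pairs(cutoff):
        ai, aj = heavy[i], heavy[j]
        ri, rj = int(topology.resindices[ai]), int(topology.resindices[aj])
        if ri == rj:
            continue
        same_chain = topology.molecule_ids[ai] == topology.molecule_ids[aj]
        if same_chain and abs(topology.resids[ai] - topology.resids[aj]) <= exclude_neighbours:
            continue
        partners[ri].add(rj)
        partners[rj].add(ri)
    return pd.Series({r: len(s) for r, s in partners.items()}, dtype=float)


def contacts_summary(trajectory: Trajectory, cutoff: float = 0.6,
                     exclude_neighbours: int = 1) -> dict:
    """Mean +/- sd of the per-residue contact count over residues and frames."""
    per_frame = [contacts_per_residue(f, trajectory.topology, cutoff,
                                      exclude_neighbours) for f in trajectory]
    table = pd.DataFrame(per_frame)
    vals = table.to_numpy().ravel()
    return {"per_residue_mean": table.mean(axis=0),
            "mean": float(vals.mean()), "std": float(vals.std(ddof=0)),
            "cutoff": cutoff, "exclude_neighbours": exclude_neighbours}
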