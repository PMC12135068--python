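"""Residue-resolved radial distribution functions against a cosolute
species and the derived associated-residue counts.

g(r) is computed between centres of mass of amino-acid residues and of
cosolute molecules (disaccharides by default), with minimal-image distances
and the standard shell-volume / bulk-density normalisation, frame-averaged.
The association criterion (the published counts come without one) defaults
to: a residue is associated when its g(r) reaches >= 1.0 somewhere within
0.8 nm; both thresholds are part of every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .md_io import Box, Topology, Trajectory, minimal_image


def _centers_of_mass(positions: np.ndarray, topology: Topology,
                     groups: list[np.ndarray]) -> np.ndarray:
    out = np.empty((len(groups), 3))
    for k, idx in enumerate(groups):
        m = topology.masses[idx]
        out[k] = (m[:, None] * positions[idx]).sum(0) / m.sum()
    return out


def residue_groups(topology: Topology, aggregate: str = "instance"):
    """Protein residue atom groups.

    ``aggregate='instance'`` keeps every residue of every chain separate;
    ``aggregate='position'`` labels residues by their within-chain number so
    equivalent residues of different chains share a row (chain-averaged map).
    """
    prot = topology.molecule_classes == "protein"
    groups, labels = [], []
    for res in np.unique(topology.resindices[prot]):
        idx = np.flatnonzero(prot & (topology.resindices == res))
        groups.append(idx)
        labels.append(int(topology.resids[idx[0]]) if aggregate == "position"
                      else int(res))
    return groups, labels


def molecule_groups(topology: Topology, cls: str) -> list[np.ndarray]:
    sel = topology.molecule_classes == cls
    return [np.flatnonzero(sel & (topology.molecule_ids == m))
            for m in np.unique(topology.molecule_ids[sel])]


@dataclass
class RDFMap:
    """Residue x r-bin matrix of g(r) plus the bookkeeping to re-normalise."""

    g: pd.DataFrame                  # rows: residue labels, cols: bin centres
    bin_edges: np.ndarray
    pair_label: str
    n_frames: int
    density: float                   # bulk cosolute number density (1/nm^3)
    raw_counts: pd.DataFrame = None  # same shape as g, mean counts per frame

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def number_integral(self) -> pd.Series:
        """Mean neighbour count within the map range, per residue."""
        return self.raw_counts.sum(axis=1)


def com_rdf(trajectory: Trajectory, cosolute_class: str = "disaccharide",
            r_max: float | None = None, bin_width: float = 0.02,
            aggregate: str = "instance",
            use_unwrapped: bool = False) -> RDFMap:
    """Per-residue COM radial distribution function versus a cosolute species.

    ``r_max`` defaults to (and may not exceed) half the smallest box length.
    """
    topo = trajectory.topology
    box = trajectory.box
    half = float(np.min(box.lengths)) / 2.0
    if r_max is None:
        r_max = half
    if box.periodic and r_max > half + 1e-12:
        raise ValueError(f"r_max {r_max} exceeds half box length {half}")
    res_groups, labels = residue_groups(topo, aggregate)
    cos_groups = molecule_groups(topo, cosolute_class)
    if not res_groups or not cos_groups:
        raise ValueError("empty residue or cosolute group")
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    nbins = len(edges) - 1
    ulabels = sorted(set(labels))
    row_of = {lab: i for i, lab in enumerate(ulabels)}
    counts = np.zeros((len(ulabels), nbins))
    rows_per_label = np.zeros(len(ulabels))
    for lab in labels:
        rows_per_label[row_of[lab]] += 1
    for fi in range(trajectory.n_frames):
        pos = (trajectory.unwrapped[fi] if use_unwrapped and
               trajectory.unwrapped is not None else trajectory.positions[fi])
        res_com = _centers_of_mass(pos, topo, res_groups)
        cos_com = _centers_of_mass(pos, topo, cos_groups)
        for k, lab in enumerate(labels):
            d = np.linalg.norm(minimal_image(res_com[k], cos_com, box), axis=-1)
            hist, _ = np.histogram(d, bins=edges)
            counts[row_of[lab]] += hist
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = len(cos_groups) / box.volume
    norm = trajectory.n_frames * rows_per_label[:, None] * shell_vol[None, :] * rho
    g = counts / norm
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFMap(
        g=pd.DataFrame(g, index=ulabels, columns=centres),
        bin_edges=edges, pair_label=f"residue-{cosolute_class}",
        n_frames=trajectory.n_frames, density=rho,
        raw_counts=pd.DataFrame(
            counts / (trajectory.n_frames * rows_per_label[:, None]),
            index=ulabels, columns=centres))


@dataclass(frozen=True)
class AssociationResult:
    height_threshold: float
    radius_threshold: float
    residues: tuple
    count: int


def associated_residues(rdf_map: RDFMap, height_threshold: float = 1.0,
                        radius_threshold: float = 0.8) -> AssociationResult:
    """Residues whose g(r) reaches the height threshold within the radius.

    Deterministic given the map; monotone in both thresholds (raising either
    the height or shrinking the radius never adds residues).
    """
    r = rdf_map.r
    if radius_threshold > r[-1] + (r[1] - r[0]):
        raise ValueError("criterion radius beyond the map range")
    within = r <= radius_threshold
    hit = (rdf_map.g.loc[:, rdf_map.g.columns[within]]
           .max(axis=1) >= height_threshold)
    residues = tuple(rdf_map.g.index[hit])
    return AssociationResult(height_threshold, radius_threshold,
                             residues, len(residues))


def export_colormap(rdf_map: RDFMap, path) -> None:
    """Residue x r CSV matrix with bin-centre header; empty bins print 0."""
    out = rdf_map.g.fillna(0.0)
    out.index.name = "residue"
    out.to_csv(path, float_format="%.6g")


def read_colormap(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(float)
    return df
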