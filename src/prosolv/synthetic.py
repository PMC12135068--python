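"""Synthetic solvated systems with known ground truth.

Real protein-solution MD trajectories are too expensive to regenerate, so
every analysis stage in this package is validated against toy systems whose
answers are known by construction:

* a solution *composition calculator* that turns mass ratios, salt content
  and counterion closure into whole-molecule counts (electroneutral by
  construction);
* Brownian and Ornstein-Uhlenbeck *walker generators* with exact diffusion
  constants / plateau amplitudes, the oracles for the scattering-function
  stack;
* a *hydrogen-bond scene builder* that places toy molecules so that the
  intended bond list (including a chosen number of protein-water-protein
  bridges) holds with margin under the default geometric criterion;
* a schematic *lysozyme stand-in* built from the real 129-residue hen egg
  white sequence with its four canonical disulfide pairs.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .md_io import Box, Frame, Topology, Trajectory

# ---------------------------------------------------------------------------
# composition calculator
# ---------------------------------------------------------------------------

#: average residue masses (Da) for a peptide chain; water added once per chain
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MOLAR_MASS = 18.01528       # Da
DISACCHARIDE_MOLAR_MASS = 342.297  # sucrose/trehalose, C12H22O11

#: hen egg white lysozyme, mature chain, 129 residues
HEWL_SEQUENCE = (
    "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNTQATNRNTDGSTDYGILQINS"
    "RWWCNDGRTPGSRNLCNIPCSALLSSDITASVNCAKKIVSDGNGMNAWVAWRNRCKGTDV"
    "QAWIRGCRL"
)
#: canonical disulfide pairs of hen egg lysozyme (1-based residue numbers)
HEWL_DISULFIDES = ((6, 127), (30, 115), (64, 80), (76, 94))


def sequence_mass(sequence: str) -> float:
    """Molar mass (Da) of a peptide chain (residue masses + one water)."""
    return sum(_RESIDUE_MASS[a] for a in sequence) + WATER_MOLAR_MASS


def sequence_formal_charge(sequence: str) -> int:
    """Net formal charge at neutral pH: (Arg+Lys) - (Asp+Glu), His neutral."""
    pos = sum(sequence.count(a) for a in "RK")
    neg = sum(sequence.count(a) for a in "DE")
    return pos - neg


@dataclass(frozen=True)
class CompositionSpec:
    """Whole-molecule composition of a protein/sugar/water/salt solution."""

    n_protein: int
    n_sugar: int
    n_water: int
    n_cation: int
    n_anion: int
    protein_charge: int
    cation_valence: int
    molar_masses: dict

    def __post_init__(self):
        for f in ("n_protein", "n_sugar", "n_water", "n_cation", "n_anion"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.total_charge != 0:
            raise ValueError(f"system not electroneutral: {self.total_charge:+d}")

    @property
    def total_charge(self) -> int:
        return (self.n_protein * self.protein_charge
                + self.n_cation * self.cation_valence - self.n_anion)

    @property
    def n_molecules(self) -> int:
        return (self.n_protein + self.n_sugar + self.n_water
                + self.n_cation + self.n_anion)

    def mass_ratios(self) -> tuple[float, float, float]:
        """(protein : sugar : water) mass ratio normalised to protein = 1."""
        mp = self.n_protein * self.molar_masses["protein"]
        ms = self.n_sugar * self.molar_masses["sugar"]
        mw = self.n_water * self.molar_masses["water"]
        return (1.0, ms / mp, mw / mp)

    def species_counts(self) -> dict[str, int]:
        return {"protein": self.n_protein, "disaccharide": self.n_sugar,
                "water": self.n_water, "cation": self.n_cation,
                "anion": self.n_anion}


def gen_solution_composition(n_protein: int = 4,
                             sugar_mass_ratio: float = 0.0,
                             water_mass_ratio: float = 2.7,
                             protein_charge: int | None = None,
                             n_cation: int = 0,
                             cation_valence: int = 1,
                             salt_concentration: float | None = None,
                             volume_nm3: float | None = None,
                             molar_masses: dict | None = None,
                             n_sugar: int | None = None,
                             n_water: int | None = None) -> CompositionSpec:
    """Build an electroneutral composition from mass ratios.

    Sugar and water counts are the nearest whole molecules realising the
    requested mass ratios relative to the total protein mass (explicit
    ``n_sugar``/``n_water`` override the ratios, since published
    compositions round these counts independently).  Anions are the
    counterion closure: one negative unit per unit of protein plus cation
    charge.  ``salt_concentration`` (mol/L) with an explicit ``volume_nm3``
    is an alternative way to set the cation count.
    """
    mm = {"protein": sequence_mass(HEWL_SEQUENCE),
          "sugar": DISACCHARIDE_MOLAR_MASS, "water": WATER_MOLAR_MASS}
    if molar_masses:
        mm.update(molar_masses)
    if protein_charge is None:
        protein_charge = sequence_formal_charge(HEWL_SEQUENCE)
    if cation_valence not in (1, 2):
        raise ValueError("cation valence must be 1 or 2")
    if salt_concentration is not None:
        if volume_nm3 is None:
            raise ValueError("salt concentration needs an explicit volume")
        # mol/L * nm^3 -> molecules (1 nm^3 = 1e-24 L, N_A = 6.02214e23)
        n_cation = int(round(salt_concentration * volume_nm3 * 1e-24 * 6.02214076e23))
    m_protein = n_protein * mm["protein"]
    if n_sugar is None:
        n_sugar = int(round(m_protein * sugar_mass_ratio / mm["sugar"]))
    if n_water is None:
        n_water = int(round(m_protein * water_mass_ratio / mm["water"]))
    n_anion = n_protein * protein_charge + n_cation * cation_valence
    if n_anion < 0:
        raise ValueError("negative implied anion count")
    return CompositionSpec(n_protein=n_protein, n_sugar=n_sugar,
                           n_water=n_water, n_cation=n_cation, n_anion=n_anion,
                           protein_charge=protein_charge,
                           cation_valence=cation_valence, molar_masses=mm)


#: published solution compositions used as presets: molecule totals and salt
#: content; water counts follow from the totals, anions from charge closure.
TABLE1_PRESETS: dict[str, dict] = {
    "LYS": dict(n_sugar=0, n_cation=0, cation_valence=1, total_molecules=8596),
    "LYS+SUC": dict(n_sugar=223, n_cation=0, cation_valence=1, total_molecules=8478),
    "LYS+TRE": dict(n_sugar=223, n_cation=0, cation_valence=1, total_molecules=8478),
    "LYS+NACL": dict(n_sugar=0, n_cation=35, cation_valence=1, total_molecules=8596),
    "LYS+SUC+NACL": dict(n_sugar=223, n_cation=34, cation_valence=1, total_molecules=8478),
    "LYS+TRE+NACL": dict(n_sugar=223, n_cation=34, cation_valence=1, total_molecules=8478),
    "LYS+ZNCL2": dict(n_sugar=0, n_cation=18, cation_valence=2, total_molecules=8596),
    "LYS+SUC+ZNCL2": dict(n_sugar=223, n_cation=17, cation_valence=2, total_molecules=8478),
    "LYS+TRE+ZNCL2": dict(n_sugar=223, n_cation=17, cation_valence=2, total_molecules=8478),
}


def preset_composition(name: str, n_protein: int = 4,
                       protein_charge: int | None = None) -> CompositionSpec:
    """Composition for a named preset system (e.g. ``LYS+SUC+NACL``).

    The water count absorbs the preset's molecule total; anion counts are
    recomputed from the counterion closure, not copied.
    """
    key = name.upper().replace(" ", "")
    if key not in TABLE1_PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(TABLE1_PRESETS)}")
    p = TABLE1_PRESETS[key]
    if protein_charge is None:
        protein_charge = sequence_formal_charge(HEWL_SEQUENCE)
    n_anion = n_protein * protein_charge + p["n_cation"] * p["cation_valence"]
    n_water = (p["total_molecules"] - n_protein - p["n_sugar"]
               - p["n_cation"] - n_anion)
    return gen_solution_composition(
        n_protein=n_protein, protein_charge=protein_charge,
        n_cation=p["n_cation"], cation_valence=p["cation_valence"],
        n_sugar=p["n_sugar"], n_water=n_water)


# ---------------------------------------------------------------------------
# walker generators (diffusive-dynamics oracles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkerSpec:
    """Point-particle dynamics: free diffusion, or OU confinement if tau_c>0.

    ``diffusion`` is D in nm^2/ps; ``tau_c`` the confinement (OU) time in
    ps; ``sigma`` the stationary per-dimension standard deviation (nm) of
    the confined walk.
    """

    n: int
    diffusion: float = 0.0
    tau_c: float = 0.0
    sigma: float = 0.1
    dt: float = 1.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.diffusion < 0 or self.dt <= 0 or self.n < 1 or self.n_frames < 1:
            raise ValueError("invalid walker spec")


def _walker_topology(n: int) -> Topology:
    topo = Topology(names=["CA"] * n, resindices=np.arange(n),
                    resnames=["ALA"] * n)
    topo.molecule_classes = np.full(n, "protein", dtype=object)
    topo.molecule_ids = np.arange(n)
    return topo


def gen_brownian(spec: WalkerSpec, box: Box) -> Trajectory:
    """Free Brownian walkers: Gaussian steps of variance 2*D*dt per axis.

    The trajectory stores both wrapped and unwrapped coordinates, so
    displacement observables need no unwrapping heuristic.
    """
    rng = np.random.default_rng(spec.seed)
    x0 = rng.uniform(0.0, box.lengths, size=(spec.n, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * spec.diffusion * spec.dt),
                       size=(spec.n_frames - 1, spec.n, 3))
    unwrapped = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
    times = spec.dt * np.arange(spec.n_frames)
    return Trajectory(_walker_topology(spec.n), np.mod(unwrapped, box.lengths),
                      times, box, unwrapped=unwrapped,
                      metadata={"generator": "brownian", "seed": spec.seed,
                                "diffusion": spec.diffusion, "dt": spec.dt})


def gen_confined_walkers(spec: WalkerSpec, box: Box | None = None) -> Trajectory:
    """Ornstein-Uhlenbeck walkers about fixed anchors (bounded motion).

    Exact discretisation: x' = a + (x-a) e^(-dt/tau) + sigma sqrt(1-e^(-2dt/tau)) xi,
    started from the stationary distribution (per-dimension variance sigma^2).
    """
    if spec.tau_c <= 0:
        raise ValueError("confined walkers need tau_c > 0")
    if box is None:
        box = Box(np.ones(3) * max(1.0, 20.0 * spec.sigma))
    rng = np.random.default_rng(spec.seed)
    anchors = rng.uniform(0.0, box.lengths, size=(spec.n, 3))
    decay = np.exp(-spec.dt / spec.tau_c)
    kick = spec.sigma * np.sqrt(1.0 - decay ** 2)
    x = anchors + spec.sigma * rng.normal(size=(spec.n, 3))
    unwrapped = np.empty((spec.n_frames, spec.n, 3))
    unwrapped[0] = x
    for t in range(1, spec.n_frames):
        x = anchors + (x - anchors) * decay + kick * rng.normal(size=(spec.n, 3))
        unwrapped[t] = x
    times = spec.dt * np.arange(spec.n_frames)
    return Trajectory(_walker_topology(spec.n), np.mod(unwrapped, box.lengths),
                      times, box, unwrapped=unwrapped,
                      metadata={"generator": "ou", "seed": spec.seed,
                                "tau_c": spec.tau_c, "sigma": spec.sigma})


# ---------------------------------------------------------------------------
# hydrogen-bond scene builder
# ---------------------------------------------------------------------------

# geometry constants (nm): an intended bond is D-A 0.28 with the H on the
# D->A axis (angle 0), leaving >=0.07 distance margin and 30 deg of angular
# margin under the default criterion (0.35 nm, H-D-A <= 30 deg)
_DA = 0.28
_DH = 0.10


@dataclass(frozen=True)
class HBondSceneSpec:
    """Designed hydrogen-bond scene: how many bonds of each category to plant.

    ``n_bridges`` (B*) waters are each double-bonded to two *distinct*
    residues of the same protein chain; ``n_same_residue_double`` waters are
    double-bonded to one residue (these must never count as bridges).
    """

    n_chains: int = 1
    residues_per_chain: int = 4
    n_pp_inter: int = 0
    n_pp_intra: int = 0
    n_pw: int = 0
    n_bridges: int = 0
    n_ww: int = 0
    n_pd: int = 0
    n_dd: int = 0
    n_dw: int = 0
    n_same_residue_double: int = 0
    n_free_waters: int = 0
    seed: int = 0


@dataclass
class SceneLedger:
    """Ground truth of a constructed scene."""

    bonds: list = field(default_factory=list)   # (donor, h, acceptor, category)
    b_star: int = 0
    category_counts: dict = field(default_factory=dict)

    def count(self, category: str) -> int:
        return sum(1 for b in self.bonds if b[3] == category)


class _SceneBuilder:
    def __init__(self, spec: HBondSceneSpec, box: Box):
        self.spec = spec
        self.box = box
        self.names, self.resnames, self.elements = [], [], []
        self.resindices, self.resids, self.chain_ids = [], [], []
        self.classes, self.mol_ids, self.positions = [], [], []
        self.donors, self.acceptors = [], []
        self.ledger = SceneLedger()
        self._next_res = 0
        self._next_mol = 0
        self._cell_iter = self._cells()
        self._chain_res = {}   # chain -> list of remaining residue slots
        rng = np.random.default_rng(spec.seed)
        self._shuffle = rng.permutation
        self._chain_high: dict[int, int] = {}
        for c in range(spec.n_chains):
            self._chain_res[c] = list(range(spec.residues_per_chain))
        self._chain_mol = {c: self._new_mol() for c in range(spec.n_chains)}

    # -- bookkeeping --------------------------------------------------------
    def _new_mol(self) -> int:
        self._next_mol += 1
        return self._next_mol - 1

    def _cells(self):
        spacing = 1.6
        nx = max(2, int(self.box.lengths[0] // spacing))
        i = 0
        while True:
            ix, iy, iz = i % nx, (i // nx) % nx, i // (nx * nx)
            if 0.8 + iz * spacing > self.box.lengths[2] - 0.8:
                raise ValueError("scene does not fit in box")
            yield np.array([0.8 + ix * spacing, 0.8 + iy * spacing,
                            0.8 + iz * spacing])
            i += 1

    def _cell(self) -> np.ndarray:
        return next(self._cell_iter)

    def _add_atom(self, name, pos, *, resindex, resid, resname, chain, cls, mol,
                  element=None) -> int:
        self.names.append(name)
        self.positions.append(np.asarray(pos, dtype=float))
        self.resindices.append(resindex)
        self.resids.append(resid)
        self.resnames.append(resname)
        self.chain_ids.append(chain)
        self.classes.append(cls)
        self.mol_ids.append(mol)
        self.elements.append(element or name[0])
        return len(self.names) - 1

    def take_residues(self, chain: int, k: int) -> list[int]:
        # residues_per_chain is a floor; chains grow when fixtures need more
        slots = self._chain_res[chain]
        hi = self._chain_high.setdefault(chain, self.spec.residues_per_chain)
        while len(slots) < k:
            slots.append(hi)
            hi += 1
            self._chain_high[chain] = hi
        return [slots.pop(0) for _ in range(k)]

    # -- molecule factories -------------------------------------------------
    def add_residue(self, chain: int, slot: int, *, n_pos, hn_dir,
                    o_pos, od_pos=None, ca_pos=None) -> dict:
        """Toy amino-acid residue: N/HN donor pair, O (+optional OD) acceptors."""
        mol = self._chain_mol[chain]
        res = self._next_res
        self._next_res += 1
        kw = dict(resindex=res, resid=slot + 1, resname="ALA",
                  chain=chr(ord("A") + chain), cls="protein", mol=mol)
        n_pos = np.asarray(n_pos, float)
        hn_dir = np.asarray(hn_dir, float)
        n = self._add_atom("N", n_pos, element="N", **kw)
        hn = self._add_atom("HN", n_pos + _DH * hn_dir, element="H", **kw)
        ca = self._add_atom("CA", np.asarray(ca_pos if ca_pos is not None
                                             else n_pos + [0.0, 0.0, 0.3]),
                            element="C", **kw)
        o = self._add_atom("O", np.asarray(o_pos, float), element="O", **kw)
        atoms = {"N": n, "HN": hn, "CA": ca, "O": o, "res": res}
        if od_pos is not None:
            atoms["OD"] = self._add_atom("OD", np.asarray(od_pos, float),
                                         element="O", **kw)
            self.acceptors.append(atoms["OD"])
        self.donors.append((n, hn))
        self.acceptors.append(o)
        return atoms

    def add_plain_residue(self, chain: int, slot: int, center) -> dict:
        c = np.asarray(center, float)
        return self.add_residue(chain, slot, n_pos=c, hn_dir=[0, 0, 1],
                                o_pos=c + [0.45, 0, 0], ca_pos=c + [0.3, 0, 0])

    def add_water(self, o_pos, h1_dir, h2_dir) -> dict:
        mol = self._new_mol()
        res = self._next_res
        self._next_res += 1
        kw = dict(resindex=res, resid=1, resname="SOL", chain="W",
                  cls="water", mol=mol)
        o_pos = np.asarray(o_pos, float)
        o = self._add_atom("OW", o_pos, element="O", **kw)
        h1 = self._add_atom("HW1", o_pos + _DH * np.asarray(h1_dir, float),
                            element="H", **kw)
        h2 = self._add_atom("HW2", o_pos + _DH * np.asarray(h2_dir, float),
                            element="H", **kw)
        self.donors.extend([(o, h1), (o, h2)])
        self.acceptors.append(o)
        return {"O": o, "H1": h1, "H2": h2, "res": res, "mol": mol}

    def add_sugar(self, center, rot=None) -> dict:
        """8-site toy disaccharide: C1 C2 + three hydroxyl (O,H) triads."""
        mol = self._new_mol()
        res = self._next_res
        self._next_res += 1
        kw = dict(resindex=res, resid=1, resname="SUC", chain="S",
                  cls="disaccharide", mol=mol)
        local = {"C1": [0, 0, 0], "C2": [0.15, 0, 0],
                 "O1": [-0.2, 0, 0], "H1": [-0.3, 0, 0],
                 "O2": [0, 0.2, 0], "H2": [0, 0.3, 0],
                 "O3": [0, -0.2, 0], "H3": [0, -0.3, 0]}
        R = np.eye(3) if rot is None else np.asarray(rot, float)
        c = np.asarray(center, float)
        atoms = {}
        for name, p in local.items():
            el = "C" if name.startswith("C") else name[0]
            atoms[name] = self._add_atom(name, c + R @ np.asarray(p, float),
                                         element=el, **kw)
        for o, h in (("O1", "H1"), ("O2", "H2"), ("O3", "H3")):
            self.donors.append((atoms[o], atoms[h]))
            self.acceptors.append(atoms[o])
        atoms["res"] = res
        return atoms

    def record(self, donor, h, acceptor, category):
        self.ledger.bonds.append((donor, h, acceptor, category))

    # -- fixtures -----------------------------------------------------------
    def fixture_pp(self, chain_a: int, chain_b: int, category: str):
        c = self._cell()
        sa, = self.take_residues(chain_a, 1)
        sb, = self.take_residues(chain_b, 1)
        ra = self.add_residue(chain_a, sa, n_pos=c, hn_dir=[0, 0, 1],
                              o_pos=c + [0.45, 0, 0], ca_pos=c + [0.3, 0, 0])
        nb = c + [0.45 + _DA, 0, 0]
        rb = self.add_residue(chain_b, sb, n_pos=nb, hn_dir=[-1, 0, 0],
                              o_pos=nb + [0.45, 0, 0], ca_pos=nb + [0.3, 0, 0])
        self.record(rb["N"], rb["HN"], ra["O"], category)

    def fixture_pw(self, chain: int):
        c = self._cell()
        s, = self.take_residues(chain, 1)
        r = self.add_plain_residue(chain, s, c)
        ow = c + [0.45 + _DA, 0, 0]
        w = self.add_water(ow, [-1, 0, 0], [0, 0, 1])
        self.record(w["O"], w["H1"], r["O"], "pw")

    def fixture_bridge(self, chain: int):
        """One water donating to the O of two distinct residues, same chain."""
        c = self._cell()
        s1, s2 = self.take_residues(chain, 2)
        w = self.add_water(c, [1, 0, 0], [0, 1, 0])
        o1 = c + [_DA, 0, 0]
        r1 = self.add_residue(chain, s1, n_pos=o1 + [0.45, 0, 0],
                              hn_dir=[0, 0, 1], o_pos=o1,
                              ca_pos=o1 + [0.3, 0, 0])
        o2 = c + [0, _DA, 0]
        r2 = self.add_residue(chain, s2, n_pos=o2 + [0, 0.45, 0],
                              hn_dir=[0, 0, 1], o_pos=o2,
                              ca_pos=o2 + [0, 0.3, 0])
        self.record(w["O"], w["H1"], r1["O"], "pw")
        self.record(w["O"], w["H2"], r2["O"], "pw")
        self.ledger.b_star += 1

    def fixture_same_residue_double(self, chain: int):
        """Water double-bonded to ONE residue (O and OD): not a bridge."""
        c = self._cell()
        s, = self.take_residues(chain, 1)
        u = np.array([1.0, 0.0, 0.0])
        ang = 2.0 * np.arcsin(0.29 / (2.0 * _DA))
        v = np.array([np.cos(ang), np.sin(ang), 0.0])
        o_pos, od_pos = c + _DA * u, c + _DA * v
        r = self.add_residue(chain, s, n_pos=c + [0.9, 0.9, 0],
                             hn_dir=[0, 0, 1], o_pos=o_pos, od_pos=od_pos,
                             ca_pos=c + [0.9, 0.6, 0])
        w = self.add_water(c, u, v)
        self.record(w["O"], w["H1"], r["O"], "pw")
        self.record(w["O"], w["H2"], r["OD"], "pw")

    def fixture_ww(self):
        c = self._cell()
        w1 = self.add_water(c, [1, 0, 0], [0, 1, 0])
        w2 = self.add_water(c + [_DA, 0, 0], [1, 0, 0],
                            [np.cos(np.pi / 4), 0, np.sin(np.pi / 4)])
        self.record(w1["O"], w1["H1"], w2["O"], "ww")

    def fixture_pd(self, chain: int):
        c = self._cell()
        s, = self.take_residues(chain, 1)
        d = self.add_sugar(c)
        o_pos = c + [0, 0.2 + _DA, 0]
        r = self.add_residue(chain, s, n_pos=o_pos + [0, 0.45, 0],
                             hn_dir=[0, 0, 1], o_pos=o_pos,
                             ca_pos=o_pos + [0, 0.3, 0])
        self.record(d["O2"], d["H2"], r["O"], "pd")

    def fixture_dd(self):
        c = self._cell()
        a = self.add_sugar(c)
        # B rotated -90 deg about z: its O3 lands at A's O2 + DA*y with the
        # O3 hydroxyl hydrogen perpendicular to the bond axis and every
        # other B hydroxyl pointing away from A: exactly one A->B bond
        rot = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        b_center = c + [0.2, 0.2 + _DA, 0]
        b = self.add_sugar(b_center, rot=rot)
        self.record(a["O2"], a["H2"], b["O3"], "dd")

    def fixture_dw(self):
        c = self._cell()
        d = self.add_sugar(c)
        ow = c + [0, 0.2 + _DA, 0]
        w = self.add_water(ow, [1, 0, 0], [0, 1, 0])
        self.record(d["O2"], d["H2"], w["O"], "dw")

    def finish(self) -> tuple[Topology, Frame, SceneLedger]:
        # park unused chain residues and free waters in their own cells
        for chain, slots in self._chain_res.items():
            for slot in list(slots):
                self.take_residues(chain, 1)
                self.add_plain_residue(chain, slot, self._cell())
        for _ in range(self.spec.n_free_waters):
            self.add_water(self._cell(), [1, 0, 0], [0, 1, 0])
        # conventional file layout: protein chains first (residues contiguous
        # and numbered per chain), then one block per solvent molecule with
        # unique residue numbers -- required for lossless GRO round trips
        n = len(self.names)
        perm = sorted(range(n), key=lambda i: (self.classes[i] != "protein",
                                               self.mol_ids[i],
                                               self.resindices[i], i))
        inv = {old: new for new, old in enumerate(perm)}
        reorder = lambda seq: [seq[i] for i in perm]
        self.names, self.resnames = reorder(self.names), reorder(self.resnames)
        self.elements, self.chain_ids = reorder(self.elements), reorder(self.chain_ids)
        self.classes, self.mol_ids = reorder(self.classes), reorder(self.mol_ids)
        self.resindices = reorder(self.resindices)
        self.positions = reorder(self.positions)
        self.donors = [(inv[d], inv[h]) for d, h in self.donors]
        self.acceptors = [inv[a] for a in self.acceptors]
        self.ledger.bonds = [(inv[d], inv[h], inv[a], c)
                             for d, h, a, c in self.ledger.bonds]
        resids, resindices = [], []
        prev_res, prev_mol = None, None
        chain_resnum, solv_resnum, res_counter = 0, 0, -1
        for i in range(n):
            if self.resindices[i] != prev_res:
                res_counter += 1
                if self.classes[i] == "protein":
                    chain_resnum = (chain_resnum + 1
                                    if self.mol_ids[i] == prev_mol else 1)
                    rid = chain_resnum
                else:
                    solv_resnum += 1
                    rid = solv_resnum
                prev_res, prev_mol = self.resindices[i], self.mol_ids[i]
                cur_rid = rid
            resids.append(cur_rid)
            resindices.append(res_counter)
        topo = Topology(names=self.names, resindices=resindices,
                        resnames=self.resnames, chain_ids=self.chain_ids,
                        resids=resids, elements=self.elements,
                        molecule_ids=self.mol_ids,
                        molecule_classes=self.classes,
                        donors=np.asarray(self.donors, int).reshape(-1, 2),
                        acceptors=np.asarray(self.acceptors, int))
        frame = Frame(0.0, np.asarray(self.positions), self.box)
        self.ledger.category_counts = {
            cat: self.ledger.count(cat)
            for cat in ("pp_inter", "pp_intra", "pw", "ww", "pd", "dd", "dw")}
        return topo, frame, self.ledger


def gen_hbond_scene(spec: HBondSceneSpec,
                    box: Box | None = None) -> tuple[Topology, Frame, SceneLedger]:
    """Construct a scene realising exactly the intended hydrogen bonds.

    Every fixture lives in its own 1.6 nm grid cell, so bonds across
    fixtures are geometrically impossible; within a fixture, placements
    satisfy the default criterion with >=0.07 nm distance margin and the
    non-bonds miss it by >=60 degrees.  Returns the ground-truth ledger
    along with the topology and frame.
    """
    if box is None:
        n_items = (spec.n_pp_inter + spec.n_pp_intra + spec.n_pw
                   + spec.n_bridges + spec.n_ww + spec.n_pd + spec.n_dd
                   + spec.n_dw + spec.n_same_residue_double
                   + spec.n_free_waters
                   + spec.n_chains * spec.residues_per_chain + 2)
        side = 1.6 * np.ceil(np.sqrt(n_items)) + 4.0
        box = Box(np.array([side, side, max(side, 8.0)]))
    b = _SceneBuilder(spec, box)
    rng = np.random.default_rng(spec.seed + 1)
    for k in range(spec.n_pp_inter):
        if spec.n_chains < 2:
            raise ValueError("pp_inter bonds need >=2 chains")
        ca, cb = rng.choice(spec.n_chains, size=2, replace=False)
        b.fixture_pp(int(ca), int(cb), "pp_inter")
    for k in range(spec.n_pp_intra):
        chain = int(rng.integers(spec.n_chains))
        b.fixture_pp(chain, chain, "pp_intra")
    for k in range(spec.n_pw):
        b.fixture_pw(int(rng.integers(spec.n_chains)))
    for k in range(spec.n_bridges):
        b.fixture_bridge(int(rng.integers(spec.n_chains)))
    for k in range(spec.n_same_residue_double):
        b.fixture_same_residue_double(int(rng.integers(spec.n_chains)))
    for k in range(spec.n_ww):
        b.fixture_ww()
    for k in range(spec.n_pd):
        b.fixture_pd(int(rng.integers(spec.n_chains)))
    for k in range(spec.n_dd):
        b.fixture_dd()
    for k in range(spec.n_dw):
        b.fixture_dw()
    return b.finish()


# ---------------------------------------------------------------------------
# schematic lysozyme stand-in
# ---------------------------------------------------------------------------

_AA3 = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}


def synthetic_lysozyme_structure(n_chains: int = 1,
                                 box_side: float = 25.0) -> tuple[Topology, Frame]:
    """Synthetic stand-in for a hen-egg lysozyme crystal structure.

    Carries the real 129-residue mature sequence and the four canonical
    disulfide pairs (Cys6-127, 30-115, 64-80, 76-94) with S-S gamma-sulfur
    distance 0.205 nm, but schematic backbone coordinates (a helical CA
    trace); sequence-derived properties (residue count, disulfide count,
    formal charge) are faithful, the geometry is not.
    """
    seq = HEWL_SEQUENCE
    names, resnames, resindices, resids, chain_ids, elements, pos = \
        [], [], [], [], [], [], []
    res_counter = 0
    for c in range(n_chains):
        origin = np.array([5.0 + 6.0 * (c % 2), 5.0 + 6.0 * (c // 2), 5.0])
        sg_pos: dict[int, np.ndarray] = {}
        for k, (i, j) in enumerate(HEWL_DISULFIDES):
            mid = origin + np.array([2.8 + 0.8 * k, -2.0, 2.0])
            d = np.array([1.0, 0.0, 0.0])
            sg_pos[i] = mid - 0.1025 * d
            sg_pos[j] = mid + 0.1025 * d
        for r, aa in enumerate(seq):
            theta = 2.0 * np.pi * r / 11.0
            ca = origin + np.array([1.2 * np.cos(theta), 1.2 * np.sin(theta),
                                    0.06 * r])
            atoms = [("N", "N", ca + [-0.12, 0.08, 0.0]),
                     ("CA", "C", ca),
                     ("C", "C", ca + [0.12, 0.08, 0.0]),
                     ("O", "O", ca + [0.18, 0.18, 0.0])]
            if aa == "C":
                atoms.append(("SG", "S", sg_pos[r + 1]))
            for name, el, p in atoms:
                names.append(name)
                elements.append(el)
                resnames.append(_AA3[aa])
                resindices.append(res_counter)
                resids.append(r + 1)
                chain_ids.append(chr(ord("A") + c))
                pos.append(p)
            res_counter += 1
    topo = Topology(names=names, resindices=resindices, resnames=resnames,
                    chain_ids=chain_ids, resids=resids, elements=elements)
    return topo, Frame(0.0, np.asarray(pos), Box(np.full(3, box_side)))


def count_disulfides(topology: Topology, frame: Frame,
                     cutoff: float = 0.23) -> int:
    """Disulfide bridges: Cys SG-SG pairs closer than ``cutoff`` nm."""
    from .md_io import minimum_distance

    sg = np.flatnonzero((topology.names == "SG")
                        & np.isin(topology.resnames, ("CYS", "CYX")))
    count = 0
    for a in range(len(sg)):
        for b in range(a + 1, len(sg)):
            if minimum_distance(frame.positions[sg[a]],
                                frame.positions[sg[b]], frame.box) < cutoff:
                count += 1
    return count


# ---------------------------------------------------------------------------
# toy solution trajectories
# ---------------------------------------------------------------------------

#: per-species rigid-body diffusion constants, nm^2/ps
DEFAULT_SPECIES_DIFFUSION = {"protein": 1e-4, "water": 2e-3,
                             "disaccharide": 5e-4, "cation": 1.5e-3,
                             "anion": 1.5e-3}


def gen_toy_solution_trajectory(composition: CompositionSpec | dict,
                                box: Box | None = None,
                                n_frames: int = 20, dt: float = 2.0,
                                residues_per_chain: int = 4,
                                diffusion: dict | None = None,
                                hbond_spec: HBondSceneSpec | None = None,
                                seed: int = 0):
    """Multi-species toy solution: a designed bond scene + rigid-body diffusion.

    The initial frame is a hydrogen-bond scene (plus ions parked in their own
    cells); thereafter every molecule performs rigid-body Brownian motion
    with a per-species diffusion constant, so the frame-0 bond ledger and
    the species composition are exact ground truth while later frames supply
    genuine dynamics.  Returns (trajectory, ledger).
    """
    counts = (composition.species_counts()
              if isinstance(composition, CompositionSpec) else dict(composition))
    spec = hbond_spec or HBondSceneSpec(
        n_chains=counts.get("protein", 1),
        residues_per_chain=residues_per_chain,
        n_pw=min(counts.get("water", 0), 2),
        n_ww=max(counts.get("water", 0) - 2, 0) // 4,
        n_dw=min(counts.get("disaccharide", 0), 2),
        seed=seed)
    topo, frame0, ledger = gen_hbond_scene(spec, box)
    box = frame0.box
    builder_counts = {"water": topo.molecule_count("water"),
                      "disaccharide": topo.molecule_count("disaccharide")}
    # top up species to the requested composition with free molecules / ions
    extra = _top_up(topo, frame0, counts, builder_counts, box)
    topo, frame0 = extra
    diff = dict(DEFAULT_SPECIES_DIFFUSION)
    if diffusion:
        diff.update(diffusion)
    rng = np.random.default_rng(seed + 17)
    n_atoms = topo.n_atoms
    unwrapped = np.empty((n_frames, n_atoms, 3))
    unwrapped[0] = frame0.positions
    mols = np.unique(topo.molecule_ids)
    mol_class = {m: topo.molecule_classes[topo.molecule_ids == m][0] for m in mols}
    atom_of_mol = {m: np.flatnonzero(topo.molecule_ids == m) for m in mols}
    for t in range(1, n_frames):
        unwrapped[t] = unwrapped[t - 1]
        for m in mols:
            step = rng.normal(0.0, np.sqrt(2.0 * diff[mol_class[m]] * dt), 3)
            unwrapped[t, atom_of_mol[m]] += step
    times = dt * np.arange(n_frames)
    traj = Trajectory(topo, np.mod(unwrapped, box.lengths), times, box,
                      unwrapped=unwrapped,
                      metadata={"generator": "toy_solution", "seed": seed,
                                "dt": dt})
    return traj, ledger


def _top_up(topo: Topology, frame: Frame, want: dict, have: dict, box: Box):
    """Append free waters/sugars/ions so species counts match ``want``."""
    names = list(topo.names)
    resnames = list(topo.resnames)
    resindices = list(topo.resindices)
    resids = list(topo.resids)
    chains = list(topo.chain_ids)
    elements = list(topo.elements)
    classes = list(topo.molecule_classes)
    mols = list(topo.molecule_ids)
    donors = topo.donors.tolist()
    acceptors = topo.acceptors.tolist()
    pos = list(np.asarray(frame.positions))
    next_res = max(resindices) + 1 if resindices else 0
    next_mol = max(mols) + 1 if mols else 0
    # park extras on a fine grid high above the scene cells
    spacing = 0.8
    nx = max(2, int(box.lengths[0] // spacing) - 1)
    slot = [0]

    def next_pos():
        i = slot[0]
        slot[0] += 1
        ix, iy, iz = i % nx, (i // nx) % nx, i // (nx * nx)
        p = np.array([0.4 + ix * spacing, 0.4 + iy * spacing,
                      box.lengths[2] - 0.4 - iz * spacing])
        if p[2] < 0.4:
            raise ValueError("composition does not fit in box")
        return p

    def add(name, el, cls, resname, chain):
        nonlocal next_res, next_mol
        p = next_pos()
        base = len(names)
        rid = max(resids) + 1 if resids else 1
        names.append(name)
        elements.append(el)
        resnames.append(resname)
        resindices.append(next_res)
        resids.append(rid)
        chains.append(chain)
        classes.append(cls)
        mols.append(next_mol)
        pos.append(p)
        if cls == "water":
            for suffix, off in (("HW1", [_DH, 0, 0]), ("HW2", [0, _DH, 0])):
                names.append(suffix)
                elements.append("H")
                resnames.append(resname)
                resindices.append(next_res)
                resids.append(rid)
                chains.append(chain)
                classes.append(cls)
                mols.append(next_mol)
                pos.append(p + off)
            donors.extend([[base, base + 1], [base, base + 2]])
            acceptors.append(base)
        next_res += 1
        next_mol += 1

    for _ in range(max(want.get("water", 0) - have.get("water", 0), 0)):
        add("OW", "O", "water", "SOL", "W")
    for _ in range(max(want.get("disaccharide", 0)
                       - have.get("disaccharide", 0), 0)):
        add("C1", "C", "disaccharide", "SUC", "S")
    for _ in range(want.get("cation", 0)):
        add("NA", "NA", "cation", "NA", "I")
    for _ in range(want.get("anion", 0)):
        add("CL", "CL", "anion", "CL", "I")
    new_topo = Topology(names=names, resindices=resindices, resnames=resnames,
                        chain_ids=chains, resids=resids, elements=elements,
                        molecule_ids=mols, molecule_classes=classes,
                        donors=np.asarray(donors, int).reshape(-1, 2),
                        acceptors=np.asarray(acceptors, int))
    return new_topo, Frame(frame.time, np.asarray(pos), box)
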