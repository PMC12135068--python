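import numpy as np
import pytest

from prosolv.md_io import Box, Frame, Topology
from prosolv.synthetic import WalkerSpec, gen_brownian


@pytest.fixture(scope="session")
def free_diffusion_traj():
    """500 free Brownian walkers, D = 0.002 nm^2/ps, 2000 frames at 1 ps."""
    spec = WalkerSpec(n=500, diffusion=0.002, dt=1.0, n_frames=2000, seed=11)
    return gen_brownian(spec, Box(np.full(3, 25.0)))


def random_water_scene(n_waters: int, box_side: float, seed: int,
                       n_residues: int = 0):
    """Randomly placed waters (+ optional standalone residues): a scene with
    no designed bonds, for detector-vs-brute-force comparisons."""
    rng = np.random.default_rng(seed)
    names, resnames, resindices, resids, chains, elements = [], [], [], [], [], []
    classes, mols, pos = [], [], []
    donors, acceptors = [], []
    res = 0

    def rand_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for c in range(n_residues):
        o = rng.uniform(0, box_side, 3)
        d1, d2 = rand_dir(), rand_dir()
        atoms = [("N", "N", o), ("HN", "H", o + 0.1 * d1),
                 ("CA", "C", o + 0.15 * d2), ("O", "O", o + 0.3 * d2)]
        base = len(names)
        for name, el, p in atoms:
            names.append(name); elements.append(el); resnames.append("ALA")
            resindices.append(res); resids.append(res + 1); chains.append("A")
            classes.append("protein"); mols.append(0); pos.append(p)
        donors.append((base, base + 1))
        acceptors.append(base + 3)
        res += 1
    for w in range(n_waters):
        o = rng.uniform(0, box_side, 3)
        d1, d2 = rand_dir(), rand_dir()
        base = len(names)
        for name, el, p in (("OW", "O", o), ("HW1", "H", o + 0.1 * d1),
                            ("HW2", "H", o + 0.1 * d2)):
            names.append(name); elements.append(el); resnames.append("SOL")
            resindices.append(res); resids.append(res + 1); chains.append("W")
            classes.append("water"); mols.append(w + 1); pos.append(p)
        donors.extend([(base, base + 1), (base, base + 2)])
        acceptors.append(base)
        res += 1
    topo = Topology(names=names, resindices=resindices, resnames=resnames,
                    chain_ids=chains, resids=resids, elements=elements,
                    molecule_ids=mols, molecule_classes=classes,
                    donors=np.asarray(donors, int).reshape(-1, 2),
                    acceptors=np.asarray(acceptors, int))
    return topo, Frame(0.0, np.asarray(pos), Box(np.full(3, box_side)))
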