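"""Shared oracle helpers used by more than one test module."""

import math

import numpy as np

from structalert.structure_io import Atom, Residue, Structure


def atom_cloud(coords, elements, chain="A"):
    s = Structure(provenance="synthetic")
    out = []
    for k, (xyz, el) in enumerate(zip(coords, elements)):
        r = Residue("GLY", k + 1, "", chain)
        r.atoms.append(Atom("CA", el, np.asarray(xyz, float)))
        out.append(r)
    s.chains[chain] = out
    return s


def mc_sasa_oracle(coords, radii, probe, n_points, seed):
    """Monte-Carlo surface sampling, independent of the spiral point set."""
    rng = np.random.default_rng(seed)
    areas = []
    ext = np.asarray(radii, float) + probe
    coords = np.asarray(coords, float)
    for i, (c, r) in enumerate(zip(coords, ext)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = c + r * pts
        free = np.ones(n_points, bool)
        for j, (c2, r2) in enumerate(zip(coords, ext)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - c2, axis=1) >= r2
        areas.append(4 * math.pi * r * r * free.mean())
    return np.array(areas)
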