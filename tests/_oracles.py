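"""Independent oracles used by the test suite.

Everything here is deliberately written as a *second*, brute-force
transcription of the quantities the package computes cleverly: a dense
assemble-and-solve FE path, a set-enumeration Euler characteristic, a
graph cycle count, and a literal transcription of the pipe-bending
geometry factor.  These stay independent of the implementation paths
they check.
"""

from __future__ import annotations

import numpy as np


def dense_fe_solve(model, apparent_strain):
    """Assemble the global stiffness densely and solve directly.

    Returns (u_full, reaction, eps_eq) with the same BC convention as
    the package solver: caudal plane fully fixed, cranial plane fixed
    laterally with prescribed axial displacement.
    """
    n = 3 * model.n_nodes
    dof = model.dofmap()
    k = np.zeros((n, n))
    for e in range(model.n_elements):
        idx = dof[e]
        k[np.ix_(idx, idx)] += model.moduli[e] * model.h_mm * model.k_unit
    kz = model.nodes_zyx[:, 0]
    caudal = np.nonzero(kz == kz.min())[0]
    cranial = np.nonzero(kz == kz.max())[0]
    u = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    for c in range(3):
        fixed[3 * caudal + c] = True
        fixed[3 * cranial + c] = True
    u[3 * cranial + 2] = -apparent_strain * model.height_mm
    free = ~fixed
    u[free] = np.linalg.solve(k[np.ix_(free, free)],
                              -k[np.ix_(free, fixed)] @ u[fixed])
    reactions = k @ u
    reaction = abs(reactions[3 * cranial + 2].sum())
    eps = np.empty(model.n_elements)
    for e in range(model.n_elements):
        ue = u[dof[e]]
        energy = 0.5 * model.moduli[e] * model.h_mm * ue @ model.k_unit @ ue
        eps[e] = np.sqrt(max(0.0, 2.0 * energy
                             / (model.moduli[e] * model.h_mm**3)))
    return u, reaction, eps


def brute_force_failure_load(reaction, eps, strain_limit=0.007,
                             volume_fraction=0.02):
    """Failure load by explicit load-scaling over the strain field.

    Sorts the strains and finds, by the linear-interpolation quantile
    convention written out longhand, the strain eps* whose exceedance
    fraction is ``volume_fraction``; the failure load scales the
    reaction by strain_limit / eps*.
    """
    srt = np.sort(np.asarray(eps, dtype=float))
    n = len(srt)
    q = 1.0 - volume_fraction
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    eps_star = srt[lo] * (1 - frac) + srt[hi] * frac
    return reaction * strain_limit / eps_star


def euler_characteristic_sets(mask):
    """chi of the voxel-cube union by explicit cell enumeration."""
    verts, edges, faces = set(), set(), set()
    cubes = 0
    for z, y, x in np.argwhere(np.asarray(mask, dtype=bool)):
        z, y, x = int(z), int(y), int(x)
        cubes += 1
        corners = [(z + dz, y + dy, x + dx)
                   for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]
        verts.update(corners)
        for axis in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    # edge along `axis` at offset (a, b) in the other axes
                    off = [0, 0, 0]
                    others = [i for i in range(3) if i != axis]
                    off[others[0]] = a
                    off[others[1]] = b
                    edges.add((axis, z + off[0], y + off[1], x + off[2]))
            for a in (0, 1):
                off = [0, 0, 0]
                off[axis] = a
                faces.add((axis, z + off[0], y + off[1], x + off[2]))
    return len(verts) - len(edges) + len(faces) - cubes


def lattice_betti1_graph(n_nodes):
    """First Betti number of the rod graph by explicit cycle counting
    (E - V + number of connected components via union-find)."""
    nz, ny, nx = n_nodes
    nodes = [(i, j, k) for i in range(nz) for j in range(ny) for k in range(nx)]
    index = {nd: i for i, nd in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    n_edges = 0
    for (i, j, k) in nodes:
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (i + d[0], j + d[1], k + d[2])
            if nb in index:
                n_edges += 1
                a, b = find(index[(i, j, k)]), find(index[nb])
                if a != b:
                    parent[a] = b
    n_comp = len({find(i) for i in range(len(nodes))})
    return n_edges - len(nodes) + n_comp


def takahashi_fb_transcription(theta_rad, rm_over_t):
    """Second transcription of the pipe-bending geometry factor."""
    x = theta_rad / np.pi
    if 5 - 1e-9 <= rm_over_t <= 10:
        coef = (rm_over_t / 8.0 - 1.0 / 4.0) ** (1.0 / 4.0)
    else:
        coef = (2.0 * rm_over_t / 5.0 - 3.0) ** (1.0 / 4.0)
    return 1.0 + coef * (4.5967 * x ** (3.0 / 2.0) + 2.6422 * x ** (106.0 / 25.0))
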