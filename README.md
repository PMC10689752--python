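# finpack

Finite sphere packings in flexible containers — the "sausage catastrophe"
from a colloid-in-vesicle point of view.

When N equal hard spheres are packed inside the tightest convex container
that holds them (the convex hull of the balls), the densest arrangement for
small N is not a compact cluster but the *sausage*: all centers on a line.
The packing fraction of a cluster is

```
eta_ch = N V0 / V_ch,      V0 = (pi/6) sigma_c^3
```

with `V_ch` the volume of the convex hull of the balls, computed exactly
here via the Steiner formula for the hull of the centers dilated by the
sphere radius r:

```
V_ch = V_hull + A_hull r + (sum_e l_e gamma_e / 2) r^2 + (4 pi / 3) r^3
```

(`gamma_e` are exterior dihedral angles; coplanar, collinear and single-point
clusters use the corresponding lower-dimensional closed forms).  The sausage
reference is `eta_lin(N) = 2N/(3N-1)`, which decreases from 1 to 2/3.

The experimental realization of this problem is colloids inside a flaccid
giant lipid vesicle: the membrane acts as the flexible container, and the
vesicle's reduced volume `nu = 3 sqrt(4 pi) V / A^{3/2}` controls whether the
enclosed colloids adopt cluster, plate or linear conformations.  The package
therefore combines:

* **geometry** — exact hull-of-balls packing fractions, sausage references,
  reduced volume (`finpack.geometry`);
* **clusters** — deterministic generators for linear, planar, FCC
  tetrahedron / octahedron / bipyramid (with regular and irregular vertex
  truncations), Mackay icosahedra and general Barlow stacks
  (`finpack.clusters`);
* **hs_projection** — mapping of externally produced coordinates to the
  hard-sphere limit (`finpack.projection`);
* **order parameters** — gyration-tensor shape anisotropy kappa^2, Steinhardt
  q6, watertight surface reconstruction of membrane bead clouds, conformation
  classification and bistability detection (`finpack.order`);
* **membrane simulator** — a desk-scale meshless membrane (orientation-
  dependent pair potential), WCA colloids, outer solvent and the solvent
  add/remove deflation protocol (`finpack.membrane`);
* **search pipeline** — the truncation catalogue that scores every cluster
  family against the sausage (`finpack.search`), plus a `finpack` CLI.

## Worked example

```python
>>> import finpack as fp
>>> t84 = fp.make_fcc_tetrahedron(7)          # regular FCC tetrahedron
>>> t84.n
84
>>> round(fp.packing_fraction_ch(t84), 5)     # exact Steiner dilation
0.66889
>>> round(fp.eta_lin(84), 5)                  # the 84-sphere sausage
0.66932
```

At N = 84 the regular tetrahedron reaches the sausage line to within 0.1%
(the crossing point of the two curves).  Removing a tetrahedral cap of 4
spheres from each vertex does better sooner:

```python
>>> from finpack.clusters import TruncationSpec
>>> t4 = fp.truncate(t84, TruncationSpec("T", 7, (4, 4, 4, 4)))
>>> t4.n, round(fp.packing_fraction_ch(t4), 5), round(fp.eta_lin(68), 5)
(68, 0.67159, 0.66995)
```

so the 68-sphere truncated tetrahedron packs *denser than the sausage*.  The
irregular search extends this into the window where the sausage was believed
optimal:

```python
>>> df = fp.truncation_search((56, 70))       # ~3 minutes
>>> sorted(set(df[df.beats_sausage].N))
[56, 58, 59, 60, 61, 62, 63, 64, 65, 66, 67, 68, 69, 70]
```

Every count in 56-70 except 57 admits a sausage-beating cluster, including
N = 58 and N = 64 (long assigned to the sausage) — and, via the greedy
partial-cap refinement, a bipyramid-derived packing at N = 63 that narrowly
beats the line (each refined cluster is a valid overlap-free packing scored
by the exact dilation, and the N = 63 case is additionally cross-checked
against a Monte-Carlo hull oracle in the test suite).

The same classifier used for the search (`kappa^2`: cluster < 0.15 <= plate
< 0.35 <= intermediate < 0.5 <= linear) drives the vesicle state analysis;
`finpack.membrane.deflate` reproduces, at reduced scale, the conformation
cycle obtained experimentally by osmotic deflation.

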