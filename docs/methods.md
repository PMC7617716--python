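# Methods

## Scope and model

`gqkit` analyzes complexes between a disordered peptide (an RGG-box-like
low-complexity region) and nucleic-acid G-quadruplexes (GQs), as produced by
docking or molecular-dynamics pipelines: multi-model PDB pseudo-trajectories
with one GQ chain set, an optional peptide chain and optional channel cations.
The analyses are purely geometric — no force field, no energetics.

A G-quartet is modelled as a directed 4-cycle in the guanine hydrogen-bond
graph: each guanine donates from its Watson–Crick edge (N1, N2) to the
Hoogsteen edge (O6, N7) of its clockwise neighbour. Two bonds per adjacent
pair give 8 per quartet and 24 for the canonical three-layer telomeric stem.
Quartet membership is frozen at frame 0 and re-scored per frame, so bond loss
registers as instability rather than re-assignment; a complex whose mean
within-quartet count drops to 15 or below (of 24) is labelled unstable —
losing two bonds in each of the three quartets is read as destabilization.

## Hydrogen-bond criterion

The criterion is geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å, plus
an H–donor–acceptor angle ≤ 30° whenever hydrogens are attached to the donor
(attachment = covalent distance < 1.25 Å). Structures without hydrogens — all
in-repo fixtures — use the distance-only heavy-atom fallback. Donor/acceptor
atoms come from fixed per-residue tables in `gqkit.config` (guanine donors
N1/N2, acceptors O6/N7/N3; protein backbone N/O plus the usual sidechain
tables; sugar–phosphate oxygens as acceptors). Each unordered atom pair is
reported once; when both directions qualify the lower-index atom donates.

Within-quartet scoring counts distinct (donor atom → neighbouring guanine)
engagements rather than raw bonds: under coordinate noise a donor can
transiently bifurcate across its neighbour's O6 and N7, and engagement
counting keeps the per-quartet maximum at its chemical value of 8.

One geometric consequence of a parallel stem at 30° twist / 3.4 Å rise is
that an upper-layer N2 sits ≈3.4 Å above the lower layer's N7. Such contacts
satisfy the Hoogsteen kind definition and appear in `detect_hbonds` output,
but they point uniformly down the stack, cannot close a 4-cycle, and are
excluded from all within-layer accounting.

## Binding modes

Per peptide residue and frame, three non-exclusive flags at a 4 Å heavy-atom
cutoff:

- **end-stacking** — within cutoff of a quartet guanine O6 (the carbonyls
  lining the central channel); optionally restricted to outer layers
  (`end_stack_outer_only`);
- **groove** — within cutoff of a groove-exposed guanine atom
  {N2, C2, N3, C4, C8, N9} (N7 can be added via `groove_include_n7`);
- **loop** — within cutoff of any atom of a connector/overhang T/U/A
  nucleotide, irrespective of backbone, sugar or base.

Interaction matrices count one contact per (residue, base, frame) regardless
of how many atom pairs qualify (switchable to atom-pair counting), and
normalize by the count of each amino-acid type in the sequence, so entries
are "contacts per residue of that type". Contact lifetime maps use the same
cutoff with a closed interval (a pair at exactly 4.0 Å counts) and a 1%
persistence filter; maps are pooled by integer contact-frame counts over
total frames, with the filter re-applied after pooling, so pooling is exact,
associative and order-independent.

## Occupancy grids

Frames are Kabsch-superposed onto the frame-0 GQ stem heavy atoms, expressed
in a canonical frame (stem principal axes, sign fixed by the first stem
atom), which makes the grid invariant under any rigid transform applied
uniformly to the trajectory. A voxel (default 1 Å) is occupied in a frame
when ≥1 peptide heavy atom falls inside it while lying within 6 Å of a GQ
heavy atom; values are occupancy fractions over frames (binary per voxel per
frame, not Gaussian-smeared density). Grid bounds cover the GQ extent plus
cutoff plus a 2 Å margin. Output is OpenDX, loadable by standard viewers.

## Conformer clustering

Conformers are featurized as all pairwise Cα distances (rotation/translation
invariant; the canonical shape descriptor for disordered ensembles), embedded
to 2-D by t-SNE (scikit-learn, seeded, PCA init) and partitioned by k-means
on the embedding. Homogeneity is the silhouette score on the embedding, since
that is the space in which the partition is made; degenerate inputs (single
cluster, identical points) report silhouette 0 with a warning. Perplexity is
config-exposed (a 50–2000 scan helper is provided); the feature vector and
perplexity are deliberate free choices, as no single convention exists.
Representatives are feature-space medoids.

## Synthetic fixtures

The generator supplies everything the tests need, in place of downloads or MD:

- **`build_gq`** places a standard planar guanine template in C4 symmetry by
  solving a small least-squares problem for the in-plane rigid transform:
  N1→O6 and N2→N7 of the clockwise neighbour at 2.9 ± 0.05 Å, cross pairs
  held beyond the 3.5 Å criterion, O6 ring radius ≈2.2 Å. Layers stack at a
  3.4 Å rise and 30° twist; (n_quartets−1) K⁺ ions sit on the axis midway
  between planes. Loop/overhang nucleotides are geometric placeholders
  (correct residue naming, P/C1′/base pseudo-atoms at large radius,
  non-clashing) — only contact/role logic is analyzed, never loop
  conformation. A self-check enforces every intra-quartet N1···O6 within
  [2.6, 3.2] Å.
- **`make_peptide_conformers`** draws self-avoiding random walks (3.8 Å Cα
  virtual bonds, 4.0 Å avoidance) with pseudo backbone N/C/O (so the peptide
  has H-bond donors/acceptors) and a CB sidechain centroid; a trace-only
  variant emits Cα/CB.
- **`place_peptide`** plants end-stacking / groove / loop / far poses by
  anchoring a designated residue's Cα near a mode-specific target atom,
  ranking candidate anchors by clearance and scanning rigid orientations
  (bulk pointed outward, widening tilt) until no peptide–GQ pair is below
  2.0 Å.
- **`make_unfolding_trajectory`** adds Gaussian coordinate noise everywhere
  plus a per-frame rigid translation of one strand along its groove normal
  (the axis-perpendicular direction through the strand's guanine centroid).
  Zero displacement with ≈0.1 Å noise keeps all 24 bonds; a few tenths of an
  Å per frame progressively severs the displaced strand's 4 bonds per layer,
  driving the mean under the 15-bond cutoff.

Hydrogens are omitted from all fixtures, so the heavy-atom fallback is the
tested default. All generators are bit-reproducible under a fixed seed.

What the fixtures do **not** emulate: real loop torsions and sugar puckers,
sequence-dependent topology (parallel/antiparallel/hybrid), solvent and ion
dynamics, physically realistic peptide secondary structure, or binding
energetics. Passing tests therefore demonstrate correctness of the geometric
operators and classifiers on controlled inputs, not the biophysics of any
particular complex; real docked/simulated PDB complexes can be fed through
the same pipeline via the config hook.

## Pipeline and problem sizes

`RunManifest` enumerates GQ-spec × conformer jobs (gq-major order). Each job
plants a pose (cycling end-stack/groove/loop), generates a 12-frame
pseudo-trajectory (noise σ = 0.08 Å; planted-unstable jobs displace one
strand 0.8 Å/frame, ≈9 Å by the final frame, which crosses the 15-bond
cutoff by construction), and writes stability series, contact maps and mode
matrices; pooled per-GQ outputs (merged contacts, occupancy grid, summed
matrices, stability scatter) follow. Jobs are isolated (failures go to a
failure table), resumable (a DONE marker keyed to the manifest hash), and
fully deterministic under the manifest seed. Default suite sizes — 8–30
frame trajectories, 3–4 conformers per run, 300–500-conformer clustering
problems — were chosen so every analysis completes in seconds while still
exercising each code path; the same operators run unchanged on full-scale
trajectories.

## Numerical choices and edge cases

- Distance comparisons are closed (≤ cutoff) throughout.
- Quartet extraction is greedy by descending incident-bond count, ties broken
  by the rotation-canonical lexicographic form of the cycle; each guanine
  joins at most one quartet. The channel axis is the principal axis of
  quartet centroids (best-fit plane normal for a single layer), oriented
  bottom-to-top.
- `classify_stability` uses "mean ≤ cutoff ⇒ unstable" (the boundary value is
  unstable), monotone in the cutoff.
- Altloc conflicts keep the highest-occupancy location; unknown residue names
  classify as `other` with a logged warning, never an error.
- Coordinates are treated as pre-imaged; no periodic minimum-image convention
  is applied anywhere (a limitation for raw periodic-box trajectories, which
  must be made whole upstream).
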