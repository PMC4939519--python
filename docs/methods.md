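# Methods

`bsite` predicts ligand-binding sites on protein chains by transferring
ligand positions from a quality-controlled database of ligand-bound template
chains. This note documents the model, its parameters, the synthetic data the
package is validated on, and the numerical choices that are not forced by the
method itself.

## The template-transfer model

The premise is structural: chains with similar folds bind ligands at
structurally equivalent pockets. Given a query chain, the method does not
model binding energetics at all — it superposes known ligand-bound chains
onto the query and asks where their ligands land, then takes consensus.

### Template database

Candidate PDB entries pass a four-stage cascade:

1. **Entry quality rules** — protein-only polymers (no DNA/RNA), X-ray
   diffraction, resolution in (0, 3.0] Å, at least one free-ligand candidate,
   and at least one chain longer than 20 residues. A "free-ligand candidate"
   is a heteroatom group declared in a HET header record, not masked by a
   MODRES record (MODRES groups are covalently modified polymer residues, not
   ligands), and not water (HOH/DOD/WAT).
2. **Chain split** — entries are split into chains; chains of ≤ 20 residues
   are dropped. The two length statements ("over 20" vs "fewer than 20
   removed") disagree at exactly 20; we keep chains of ≥ 21 residues.
3. **Ligand size** — a chain survives only if it owns a ligand with ≥ 6 heavy
   atoms. Hydrogens never count: crystal structures resolve them
   inconsistently, so counting them would make the rule
   deposition-dependent.
4. **Complex stability** — the binding site of a ligand is every chain
   residue with a heavy atom within 8 Å of any ligand heavy atom. The
   complex is *stable* when some ligand atom lies within 4 Å of the
   geometric (unweighted, heavy-atom) center of the site. This rejects
   crystallization additives sitting on flat surface patches, whose
   one-sided site shell has a center far from the ligand. A chain enters the
   database if at least one of its ligands is stable; unstable ligands are
   dropped from the entry.

Surviving chains are indexed two ways: by a fold-classification string
(taken verbatim from an external SCOPe-style mapping file, never computed)
and by chain length, sorted for binary search.

### Prediction workflow

Each query chain takes the first applicable route:

- **Part 1 (bound)** — the chain carries a ligand passing the size and
  stability gates: the site is read off directly (8 Å residue shell, one
  site per stable ligand, ranked by ligand heavy-atom count). A bound chain
  whose ligand fails stability is stripped of its ligands and treated as
  unbound.
- **Part 2 (homology search)** — templates sharing the query's
  classification string are the candidates.
- **Part 3 (length search)** — with no usable homologous template,
  candidates are templates whose length differs from the query's by
  strictly less than 30 % (relative to the query). Part 2 also falls
  through to Part 3 when every homologous candidate is rejected downstream.

On routes 2–3 the query is aligned against every candidate (below), each
template's ligands are mapped into the query frame by the alignment
transform, and templates whose mapped ligand fails the same 4 Å/8 Å
stability gate against the *query* are discarded. The survivors are ranked
by alignment similarity and at most the top 20 kept.

### Structural alignment (CE-lite)

A combinatorial-extension style aligner on CA atoms only:

- **AFP detection** — all window pairs of 8 residues whose internal CA–CA
  distance matrices agree to a mean absolute difference ≤ 3.0 Å. Distance
  matrices are pose-invariant, so this stage (and the next) is unaffected by
  how either chain is oriented.
- **Path extension** — dynamic programming chains AFPs into the best
  sequential path: successors must advance in both chains; same-diagonal
  AFPs may overlap (their pairs coincide); off-diagonal joins must be
  disjoint with gaps ≤ 30 residues in each chain and a cross-fragment
  distance-matrix difference ≤ 4.0 Å. The objective is maximal aligned pair
  count, ties broken by the smaller summed AFP difference. A deterministic
  beam (24 best AFPs per query window, by difference) bounds the DP graph;
  it only matters on dissimilar pairs where thousands of incidental window
  matches would otherwise dominate the cost.
- **Superposition** — one Kabsch (SVD) fit on the paired CA coordinates
  gives the template→query transform and the RMSD. Reflections are never
  returned; collinear or < 3-point inputs are rejected.
- **Similarity score** — `(aligned_length / min(n_q, n_t)) · 1/(1 + rmsd/3 Å)`,
  bounded in [0, 1] and exactly 1 for a full-length zero-RMSD alignment.
  The score is our own definition (the ranking notion is otherwise left
  open); it is length-normalized so short spurious matches cannot outrank
  full-fold agreement, and it is config-replaceable. Ranking ties break by
  lower RMSD, then template id, so runs are reproducible.

### Consensus clustering of mapped ligands

Mapped-ligand *geometric centers* are clustered by iterative election: count,
for every remaining ligand, the other remaining centers strictly within the
cluster radius (default 3.0 Å, valid 1–8 Å); elect the ligand with the
largest count (ties: best-ranked template, then input order); remove it and
every center within the radius; recount from scratch; stop after 3 sites or
exhaustion. The elected ligand's center is the predicted site center and its
10 Å residue shell is the predicted site (a config flag widens the shell to
the whole cluster). No cluster count needs to be specified in advance, and
the radius has a physical meaning — how far apart two template ligands in
the same pocket may sit.

Boundary conventions: site-membership radii (8, 10 Å) and the 4 Å
stability/hit thresholds are closed (≤); the clustering count radius is open
(<). Election counts exclude the candidate's own center (a self-count is a
constant shift and cannot change the argmax); the reported support is the
cluster size including the elected ligand, so supports over all sites sum to
at most the number of mapped ligands.

### Evaluation

- **Center hit** — a predicted site is correct when its center lies within
  4 Å of any heavy atom of the experimentally observed ligand; Top1/Top3
  rates follow. (The criterion's wording can be read with predicted and true
  roles swapped; we score the predicted center against the true ligand's
  atoms, the only ground truth available.)
- **Residue-level MCC** — residues are partitioned into
  predicted/experimental site and non-site sets (experimental site = 8 Å
  shell of the held-out ligand); the Matthews correlation coefficient is
  computed from the resulting confusion counts, with any zero factor in the
  denominator giving 0 (the standard convention). A bound chain that passes
  the stability gate scores accuracy 100 % and MCC 1 by definition, without
  running a prediction.

## Synthetic validation data

No external structures are downloaded; everything is generated.

A fixture "protein" is a CA + pseudo-CB trace: a spherical-spiral *cage* of
residues (radius ≈ 5.8–7.4 Å, family-specific) wrapped around a pocket, with
random-walk segments before and/or after it (CA step 3.8 Å, turning
amplitude redrawn every step so local geometry is distinctive along the
chain). The ligand (default 8 heavy atoms on a 1.4 Å shell) is placed at the
fixed point of the site-center map — moved to the heavy-atom center of its
own 8 Å shell until the two agree — so the stability gate holds by
construction for defect-free fixtures.

A *fold family* is one canonical backbone drawn from the family's random
stream; where the cage sits along the sequence, its radius and spiral
coverage are family properties. Members are the canonical shape plus
homolog-like variation: per-atom jitter (σ = 0.30 Å), ragged termini (0–3
residues trimmed per end, never into the cage), and a random rigid motion.
Two design points matter and were learned the hard way:

- families must differ in *global architecture*, not just local wiggle —
  otherwise even wrong-family alignments map ligands coherently onto the
  query's pocket region and manufacture spurious consensus clusters;
- members must not be identical copies — four identical wrong templates
  produce four identical wrong mappings, i.e. an automatic tight cluster.
  Member jitter and ragged termini decorrelate wrong alignments (which are
  marginal and flip between local optima under perturbation) while leaving
  correct alignments intact.

Engineered defects each break exactly one cascade stage: `nmr` and
`high_resolution` (entry rules), `short_chain` (an extra 15-residue chain for
the length filter), `small_ligand` (5 atoms) and `modres_mask` (ligand masked
by MODRES; a 3-atom decoy HET group keeps the entry-level free-ligand
predicate true) for the size stage, and `unstable_ligand` (placed off the
tail end, one-sided shell) for the stability stage. Unbound queries are
derived from bound fixtures by deleting ligands, applying a seeded rigid
motion, and adding Gaussian coordinate noise; the ground truth is transported
through the same motion. All outputs are byte-reproducible from their seeds.

What passing on these fixtures does *not* show: the generator has no side
chains, no chemistry, no conformational change on binding, no
crystallographic artifacts beyond the engineered defects, and its fold
variety is far narrower than a real fold library. Results on it validate the
pipeline's logic and geometry, not attainable accuracy on real PDB data.

## Problem sizes and study conditions

Validation uses corpora of 3–5 families × 4 members of 60-residue chains
(the cascade corpus: 2 × 5 with one defect per entry), 20 unbound queries
with σ = 0.25 Å noise, and the default thresholds throughout. These sizes
make each full run a few minutes on one core while leaving every code path
exercised; the alignment stage dominates the cost (O(n²) window comparison
plus the DP).

Observed behavior under these conditions: the homology route recovers the
held-out ligand position (Top1 within 4 Å) for 20/20 queries; the
length-index route, which must reject 16 wrong-fold templates per query with
no classification help, recovers 18–20/20 depending on the corpus seed —
its occasional misses are wrong-fold consensus clusters that outvote the
true family's four templates, and the true site is then typically Top2.
Unbound mean Top1 MCC is ≈ 0.92.

## Known limitations

- Sequential (monotone) alignments only; no circular permutations, no
  iterative superposition refinement after the DP path.
- One model per PDB entry (model 1); no assembly/symmetry expansion; no
  mmCIF input.
- Interface ligands are assigned to a single chain (the deposited chain id,
  or the nearest polymer chain when that id has no polymer residues); they
  never seed templates for two chains.
- The similarity score is a pragmatic invention; rankings on real data are
  not comparable bit-for-bit with any particular CE implementation.
- With a small candidate pool the top-20 cut is vacuous and low-similarity
  templates reach clustering; a large database fills the top-20 with true
  homologs, which is the regime the method is designed for.
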