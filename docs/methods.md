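# Methods

This note documents the models, parameter choices and numerical decisions
behind `allopath`, and what the synthetic-data validation does and does not
demonstrate about real molecular-dynamics data.

## Ensembles and residue addressing

An `Ensemble` is an ordered stack of coordinate frames (Å) over one shared
atom topology, read from multi-model PDB files. Residues are addressed
everywhere by author keys `(chain, residue number, insertion code)`, never
by sequential index, so selections survive numbering gaps. Alternate
locations are collapsed at ingestion by highest occupancy (ties prefer
altloc `A`, then lexicographic), a deterministic rule chosen so the same
file always yields the same ensemble. Waters are dropped by default and
non-protein residues never enter networks; hydrogens are retained in the
topology but excluded from side-chain pair counting unless requested,
matching the heavy-atom convention of the structure-network literature.

## Protein structure network

For each frame, `n_ij` counts side-chain heavy-atom pairs of residues i and
j within the contact cutoff (default 4.5 Å; glycine contributes its Cα).
The interaction strength is

    I_ij = 100 · n_ij / √(N_i · N_j)   (percent).

The square-root normalization is the standard form of the PSN literature
and is the default; a `normalization="product"` switch gives the literal
product form for comparison. Normalization factors default to the
"uniform" mode N = 100 for every residue type — making I_ij a plain scaled
pair count — because no published per-type table is bundled; a user TSV of
per-residue-type values can be supplied instead (`"table"` mode). Nodes are
connected when `I_ij ≥ I_min` **and** at least one atom pair is in contact;
`I_min` defaults to 3.0% and is echoed into every pipeline report because
results are sensitive to it. Sequence-adjacent residues of the same chain
are excluded from edges by default (standard practice; it prevents trivial
backbone-threaded paths), with a flag to include them.

## Dynamic cross-correlation

DCC is computed on one atom per residue (Cα):

    C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),

with displacements taken about the ensemble mean after an optional
least-squares (Kabsch, proper rotations only) superposition of every frame
onto that mean; the fit-and-remean cycle runs twice, which in practice
converges the mean. Residues with zero displacement variance are flagged,
zeroed, and excluded from correlation-filtered path searches rather than
producing NaNs. Values are clipped to [−1, 1] against rounding.

## Communication pathways

Path searches run per frame on the subgraph whose edges satisfy
`|C_ij| ≥ corr_min` (default 0.3, configurable and always reported): the
correlation filter acts on edges, which subsumes endpoint filtering and is
the strictest of the defensible readings. The search minimizes hop count
(unit edge cost); among equal-hop paths it maximizes summed interaction
strength, then takes the lexicographically smallest residue sequence —
fully deterministic tie-breaking, implemented as BFS layering plus a
backward dynamic program over the shortest-path DAG, and verified against
exhaustive simple-path enumeration on hundreds of random graphs.

For a pocket pair, every (source residue, sink residue) combination is
searched in every frame; identical residue sequences are pooled, counted at
most once per frame, and a path's *frequency* is its supporting-frame
fraction. The number of distinct sequences with frequency ≥ 30% is the
reported pathway count, and the single highest-frequency sequence the main
pathway. Per-frame networks are a modelling choice forced by the notion of
frequency itself; alternatives (pair-weighted counts, time-averaged
structures) would not yield per-path frequencies.

## Clustering and representatives

Frames are compared by best-fit RMSD over a stated atom selection
(backbone of the interface residues in the intended use). k-means needs a
vector space, so the RMSD matrix is embedded by classical (Torgerson) MDS
into at most `min(n_frames − 1, 10)` dimensions keeping only positive
eigenvalues; k-means (scikit-learn, best of `n_init` seeded restarts) runs
there. Each class is represented by its *medoid* — the member frame with
the least summed RMSD to its cluster, ties to the lowest frame index —
because the representative must be an actual conformation, not an average.
`k` is a configuration parameter (8 in the motivating workflow); no
automatic selection is attempted.

## Geometry

SASA uses the Shrake–Rupley construction with 960 golden-spiral points per
atom and probe radius 1.4 Å; the bundled van der Waals radii are Bondi-type
by element and overridable. 960 points keep the isolated-atom and
two-sphere closed forms within 2%, the tolerance asserted in the tests.
Contact area is the symmetric buried-surface difference
`(SASA_A + SASA_B − SASA_AB)/2` over heavy atoms, floored at zero against
quadrature noise. Pocket volume is a POVME-style count of 0.5 Å grid
points inside an inclusion sphere (centered on the pocket-lining centroid
by default) and outside every solvent-expanded atom; halving the spacing
moves fixture volumes by under 3%.

## MM-PBSA bookkeeping

The derived columns are exact row-wise sums in a fixed order —
`E_gas = E_int + E_ele + E_vdw`, `G_sol = G_psolv + G_npsolv`,
`G = E_gas + G_sol` — and the identities are asserted to 1e-12.
Conformational entropy is deliberately not modelled. The Poisson–Boltzmann
polar term is always an input column, never solved. Binding energies follow
the single-trajectory convention (frame-wise differencing, equal frame
counts required) with a flag for the multi-trajectory mean-difference
convention. Reported spreads are sample standard deviations (n − 1) over
frames. The nonpolar solvation term is γ·SASA with γ = 0.0072
kcal/(mol·Å²). Hot-spot residues are those with mean contribution
*strictly* below −1 kcal/mol, sorted most favorable first.

## Screening evaluation

Scores follow the docking convention (lower = stronger) by default, with
an explicit higher-is-better flag. The ROC places one vertex per distinct
score value so tied scores advance TPR and FPR jointly; the trapezoidal
area then equals the Mann–Whitney statistic with ties credited 1/2 — the
standard unbiased estimator — which the property tests assert to 1e-12 on
randomized tables. Rule-of-five thresholds are inclusive (a molecule at
MW 500, logP 5, 10 acceptors, 5 donors passes); the lenient one-violation
variant is selectable.

## Synthetic ground truth: what it shows and what it does not

*GNM ensembles.* Frames are sampled, per Cartesian axis, from the Gaussian
with covariance `scale × pinv(Kirchhoff)` around a self-avoiding pseudo-Cα
chain (bond 3.8 Å, clash 3.4 Å, contact cutoff 7 Å). The resulting
analytic correlation matrix is the exact expectation of the DCC estimator,
so DCC recovery can be tested quantitatively (0.05 RMS at 5,000 frames, a
size chosen so the sampling error ~1/√n sits well inside that bound). A
GNM was chosen over more realistic elastic models precisely because this
ground truth is closed-form.

*Planted-path dimers.* Residues are laid out on widely separated contact
components: the planted residue chain, persistent decoy contact pairs, and
isolated singletons. Contacting residues sit 9 Å apart with side-chain
pseudo-atom tips extending 2.6–3.0 Å toward each other ("on", minimum
inter-tip pair count 4) or retracted to ≤1.3 Å ("off", nearest pair
> 6 Å), with 0.05 Å thermal jitter — margins large enough that no jitter
can flip a contact. Interior path residues carry 4 side-chain pseudo-atoms
(2 per contact direction) and terminal ones 3; with fewer atoms an interior
residue could present only one atom toward a neighbor and the edge would
fall below the package's own default `I_min = 3`. A shared per-frame
displacement (σ = 0.3 Å) moves all planted residues coherently so their
DCC exceeds the default `corr_min`, as correlated-motion pathways should.
Persistence is realized as an exact seeded frame subset
(`round(p·n_frames)` "on" frames), so the tallied frequency equals the
requested persistence exactly and binomial-interval checks hold trivially.
Decoy pairs never touch pockets or the path, making the planted chain the
unique source→sink route (verified by exhaustive enumeration).

*Score and energy tables.* Active scores are N(−d, 1) against N(0, 1)
decoys, giving the closed-form expected AUC Φ(d/√2); the default set size
(40 actives, 1,440 decoys) mirrors a realistic antagonist/decoy screen at a
1:36 ratio. Energy tables are independent Gaussians per component.

These generators validate the *estimators and bookkeeping*, not the
physics: they contain no force field, solvent, membrane, rotamers, or
docking poses, and their contact geometry is schematic. Passing tests
demonstrate that the network construction, correlation estimation, path
search, clustering, geometry and energy code compute what they claim on
data whose truth is known — not that any particular biological system will
show a given pathway count or AUC.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; generators derive
independent child streams from one root seed, so partial reruns reproduce.
Pipeline reports contain no wall-clock content and serialize with sorted
keys: identical config + seeds give byte-identical reports. Test problem
sizes (25–30 residue GNM chains, 5,000-frame correlation recovery, 200-frame
persistence checks, 500-graph path oracles, 1,000-replicate AUC means) were
chosen as the smallest sizes at which the statistical assertions have
comfortable margins.

## Known limitations

* PDB only (no mmCIF or binary trajectory formats); structures above PDB
  field widths (>9999 residue numbers) are rejected rather than renumbered.
* The PSN normalization table ships empty; uniform mode makes I_ij a scaled
  pair count, which changes the absolute meaning of `I_min` relative to
  published per-type normalizations.
* Pathway counting reports distinct residue sequences; other tallies seen
  in the literature (per-pair counts, per-frame totals) are not emulated.
* SASA is O(atoms × neighbors × points) pure Python/NumPy — adequate for
  ensembles of a few hundred atoms per frame, slow for full receptors at
  high point counts.
* The entropy term of end-state binding energies is out of scope by design.
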