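# Methods

`nmvar` implements an entropy-based normal-mode approach to
genotype–phenotype correlation for missense variants of a multi-chain
protein complex (the motivating case is TUBB4A-related
hypomyelinating leukodystrophy, with the tubulin–stathmin-like-domain
complex as the structural template). This note records the model, its
assumptions, the numerical choices, and what the synthetic tests do and
do not establish.

## Coarse-grained structure model

A structure is reduced to one node per amino-acid residue at its Cα
position, plus one node per heavy atom of each bound ligand (GTP/GDP by
default), typed `LIG`. Waters and unrecognized heteroatoms are dropped;
alternate locations resolve to the highest-occupancy conformer;
insertion codes are preserved in node keys. Coordinates are
canonicalized to PDB precision (3 decimals) so repeated reads and
generator round-trips are bit-identical.

Subunit labelling designates one *mutable* chain (default B, modelling a
heterozygous, autosomal-dominant mutation carried by a single copy) and
assigns every other protein chain its own subunit label; all ligand
nodes form the ligand subunit (default label K). Downstream entropy
differences are read only off these bystander subunits: the question is
how a mutation in chain B perturbs the dynamics of everything *else*.

Both "humanization" (replacing a template chain's sequence with a target
species' sequence) and point mutagenesis operate purely on residue
identity. No coordinate ever moves. This deliberately replaces all-atom
side-chain rebuilding: the elastic network below is sequence-aware, so an
identity change alters the dynamics while the crystal geometry — and
therefore comparability between wild type and variant — is exactly
preserved. Humanization aligns the chain against the target with a
global BLOSUM62 alignment (gap open −11, extend −1); alignments below a
70% identity floor, or with internal gap runs longer than 10 columns,
are rejected rather than trusted. The same alignment provides the map
from target (human) residue numbering to structure (author) numbering;
catalog positions that do not map raise an error instead of being
silently skipped. Percent identity and percent "similarity" (identical
plus positively-scoring pairs, BLAST-style positives) are both reported,
since published similarity figures rarely state which was meant.

## Sequence-aware elastic network

Nodes are joined by springs of two kinds:

- **backbone**: sequential residues (author-numbering difference 1)
  within a chain, stiffness `k_backbone` (default 100);
- **nonbonded**: every other pair within `cutoff_radius` (default 12 Å),
  stiffness `epsilon_nonbonded * w(t_i, t_j)` where `w` is a symmetric
  residue-type pair weight table; pairs involving a ligand node use
  `ligand_weight` (default 1).

The default weight table is a contact-propensity surrogate derived from
Kyte–Doolittle hydrophobicity: `w(a,b) = exp(beta * (h_a + h_b)/2)` with
`beta = 0.15`, normalized to mean 1 over the 20×20 table, spanning
roughly 0.5–2. Hydrophobicity is the dominant axis of knowledge-based
contact potentials, and this form is fully derivable from a constant
shipped with Biopython — unlike a transcribed contact-energy matrix, it
can be regenerated and audited in-repo. The table is injectable through
`EnmParams`, so a Miyazawa–Jernigan-derived or ENCoM-derived table can
be dropped in without touching any other code. What matters for the
method is only the defining property: a point mutation changes spring
stiffnesses, hence the vibrational spectrum, without moving atoms.

The Hessian is the standard anisotropic-network form: each spring
contributes `-k r̂ r̂ᵀ` off-diagonal 3×3 blocks, diagonal blocks enforce
zero row-block sums. Unit masses throughout (no mass weighting). The
full dense symmetric eigendecomposition is always computed, because the
entropy sums run over all modes. Eigenvalues below
`zero_mode_tol × λ_max` (default 1e-8) count as rigid-body modes; a
connected non-collinear network has exactly six. Disconnected networks
are rejected by default (`on_disconnected="error"`); callers can keep
them flagged or restrict to the largest component.

## Entropic profile and ΔG

The per-node "entropic profile" is the harmonic
mean-square-fluctuation surrogate

    S_i = Σ_{m not rigid} |v_{m,i}|² / λ_m ,

i.e. the per-node trace of the Hessian pseudo-inverse — the standard
harmonic proxy for per-residue conformational entropy. The scalar
`−Σ ln λ_m` is exported alongside. Units are arbitrary; the method uses
only differences and their correlations, never absolute values.

ΔG is the difference **variant − wild type**, restricted to the
bystander subunits (A, C, D, E, K in the tubulin case; the mutated chain
is excluded). Positive values mean the variant is more mobile at that
node. The opposite sign convention appears in the literature; since
every downstream quantity is a Pearson correlation of ΔG vectors, the
choice is immaterial and is fixed here once, in `DeltaGProfile`.

## Hotspots, dendrograms, concordance

**Structural clusters.** A hotspot is a set of variant Cα positions
whose mean distance to the set's center of mass is below 15 Å. The
search is greedy seeded growth: every variant seeds a cluster, the
nearest remaining variant (to the running center of mass) is added while
the criterion holds, and maximal member sets are deduplicated. This was
chosen because it is deterministic, order-independent (canonical
position-then-name ordering with lowest-index tie-breaks) and naturally
produces partially overlapping clusters. Note one property of any
mean-to-center criterion: a tight group can absorb a single remote
variant if the group is large enough, so "overlap" regions should be
read alongside the per-cluster mean distances, which are always emitted.

**Correlation and Ward trees.** Within a hotspot, every variant pair's
ΔG vectors (per subunit, and concatenated as "combined") are compared by
Pearson correlation, converted to the distance `d = √(2(1−r))` — so
identical profiles merge at height 0 and perfectly anticorrelated ones
sit at the maximum 2 — and clustered with Ward's method (Lance–Williams
update, as implemented in scipy). Alternative distance choices (1−r, or
Euclidean distance on ΔG directly) are isolated behind
`correlation_to_distance`. Dendrograms are exported as Newick (branch
length = parent merge height − child merge height) plus a JSON linkage
dump. A zero-variance ΔG vector leaves r undefined; the default is a
hard error naming the variant, with an explicit `constant_policy="zero"`
(r = 0, "no information") available for null synthetic panels.

**Concordance score.** The qualitative claim "the tree orders variants
along the clinical continuum" is quantified as the Spearman rank
correlation between cophenetic distance and absolute severity difference
over all variant pairs, in [−1, 1]. Severity is an ordinal scale over
phenotype groups (default `0 < 1 < 2 < 3b < 3a < 4 < 5`, configurable —
benign controls mildest, early-infantile encephalopathy most severe;
the 3b-below-3a placement reflects its milder course). Per cluster, the
best-scoring subunit is reported, mirroring the observation that each
hotspot has at least one allosterically informative subunit. A
label-permutation null is provided for calibration.

**Transitions.** Cluster pairs sharing variants are listed; a transition
is flagged "interrupted" when two shared variants have a small ΔG
distance (below a configurable quantile, default 0.25, of all panel
pairwise distances) yet different phenotype groups — entropically
similar but clinically distinct.

## Synthetic data: what it emulates, and what green tests mean

`make_toy_complex` generates helical-bundle / ring / lattice multi-chain
complexes (defaults: 5 chains × 38–40 residues + 10 ligand-like nodes,
≈200 nodes — the smallest scale at which two 15 Å hotspots and five
bystander subunits coexist) with seeded random sequences and a clash
guard (min inter-node distance > 1 Å). `make_variant_panel` plants
variant families on the mutable chain: each family substitutes to its
own characteristic residue type, and the returned weight table scales
that type's contacts by `(1+effect_size)` (stiffening families) or
`1/(1+effect_size)` (softening). At `effect_size = 0` the table is
uniform and every variant is an exact null (ΔG ≡ 0). "Clustered"
placement packs each family into a 15 Å ball around well-separated
centers; family phenotype labels reuse the catalog vocabulary so the
concordance scorer runs unchanged.

The default `effect_size = 2.0` was fixed a priori; a single seeded
sweep (seeds 0–9; effects 0.5, 1, 2) confirmed family recovery
(Ward cut at the family count, combined profiles) at ARI = 1.0 for all
tested nonzero effects, and chance-level recovery at zero effect. The
value was pinned unchanged.

Green synthetic tests establish that the machinery — mutation →
spectrum shift → ΔG correlation → Ward recovery — is internally
consistent and sensitive in the stated direction. They do **not**
establish anything about real tubulin: the toy geometry is not tubulin,
the weight table is a hydrophobicity surrogate rather than a fitted
potential, and real variant effects are not constructed to be family-
aligned. Reproducing published dendrogram topologies for the real
complex would additionally require the exact original NMA
parameterization, which this package intentionally replaces with a
documented, testable approximation; the external reproduction (real PDB
entry 1FFX plus porcine/human sequences) is therefore an optional,
download-dependent exercise, not part of the test surface.

## Numerical policy, determinism, limitations

- Dense `scipy.linalg.eigh` everywhere; an independent solver
  (`numpy.linalg.eigh`) and a Moore–Penrose-pseudo-inverse route serve
  as oracles in tests, never as the implementation.
- All tie-breaks are lowest-index/canonical-order; all generators are
  seeded `numpy.random.default_rng`; pipeline outputs are checksummed
  and rerun-identical.
- Degenerate inputs fail loudly: missing Cα, reference-residue
  mismatches (numbering drift guard), unmappable catalog positions,
  disconnected networks, constant ΔG vectors, all-equal severity labels.
- No anharmonicity, no solvent, no temperature dependence, no absolute
  free energies: "ΔG" here is a vibrational-entropy difference and is
  treated strictly relatively.
- The greedy hotspot search is one defensible reading of the 15 Å
  criterion; other cluster-search rules satisfying the same invariant
  exist and would yield different overlap structure. The threshold and
  the transition quantile are configuration keys, not constants.
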