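# Methods

## Solvent accessibility and region assignment

Per-atom SASA uses Shrake–Rupley sphere sampling over heavy atoms: a
deterministic golden-spiral quadrature (default 960 points/atom), probe
radius 1.4 Å, and Bondi van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80, Se 1.90 Å). Hydrogens present in a file are retained in the model
but ignored by the quadrature, since typical X-ray inputs lack them and the
MaxASA reference values are heavy-atom quantities. The quadrature is exact
for an isolated sphere and agrees with the two-sphere spherical-cap closed
form to ≲0.3 % at the default resolution; doubling the point count changes
per-residue values by well under 1 Å² on the bundled fixtures.

Relative accessibility divides residue ASA by its maximum attainable value.
Three MaxASA scales are bundled — one theoretical and two empirical
Gly-X-Gly tables — because the consensus vote across normalization scales
is part of the region definition. The reported rASA uses the first scale;
the consensus label is the majority over all scales, with ties resolved by
the fixed priority core > support > rim-interacting > rim-NIS > surface >
interior (the more-buried label wins; the vote needs *some* deterministic
tie-break and burial is the property the classification is about). rASA
values above 1 occur for residues more exposed than the reference state and
are kept unclamped: clamping would silently distort ΔrASA.

Boundary semantics follow the strict inequalities of the rASA rules: a
residue sitting exactly at the 25 % cut on both sides of binding falls into
the rim branch. Interface membership (ΔrASA > 0) and the 5 % rim-NIS cut
are tested with a 1e-9 tolerance to absorb quadrature round-off.

Monomer contexts are the chains extracted from the complex without
re-minimization, so any induced-fit effect present in the bound coordinates
is shared by both contexts, and monomer/complex coordinates are
bit-identical.

Buried surface area is the per-residue monomer-minus-complex difference,
clamped at zero and summed over both chains; summed this way it equals
ASA_A + ASA_B − ASA_complex, and the per-region sums conserve the total by
construction.

## Structure normalization

Parsing (PDB and mmCIF) is delegated to gemmi. Only the first model of
multi-model files is used. Non-amino-acid heteroatoms are excluded from the
residue lists but counted in provenance. Alternate conformers are reduced
to one per atom — highest occupancy, ties broken by altloc character — so
repeated runs see identical coordinates. Residues missing expected heavy
atoms are flagged incomplete but retained; selenomethionine and
selenocysteine are kept with their selenium atoms and classified through
their sulfur analogues.

## Interaction detection

Candidate pairs are residues with Cα–Cα ≤ 14 Å ("less or equal" — a pair at
exactly 14.0 Å is retained), found by a KD-tree and emitted in a
deterministic key order. Intra-chain enumeration (used for interior
statistics) additionally requires a sequence separation of at least 2 to
exclude trivially bonded neighbors.

Every detector evaluates internal distances and angles only, so output is
rigid-motion invariant; all thresholds are `GeometryConfig` fields with
literature-informed defaults, overridable from a flat key=value file.
Distance criteria use ≤ semantics. The defaults:

| criterion | default |
|---|---|
| H-bond donor–acceptor / angle | 3.5 Å / ≥ 120° |
| S/Se-mediated H-bond | 4.0 Å |
| H–π (H to centroid, cone) | 3.5 Å / 45° |
| n→π* (O···C, Bürgi–Dunitz window) | 3.2 Å / 95–125° |
| C-bond, chalcogen (σ-hole axis) | 3.6 Å / ≥ 140° |
| aromatic–aromatic centroids | 7.0 Å (stacked ≤ 30°, T-shaped ≥ 60°) |
| amino–π / aromatic–S/Se | 5.5 Å, π-face cone 45° |
| aromatic–charge centroids | 6.0 Å |
| salt bridge N···O | 4.0 Å + H-bond geometry |
| ARG–ARG guanidinium centroids / tilt | 5.0 Å / ≤ 30° |
| van der Waals | r_i + r_j + 0.5 Å |
| hydrophobic closest side-chain C–C | 5.0 Å |
| clash/repulsion backbone / side chain | 8.0 Å / 5.0 Å (minimum atom distances) |

Because the inputs rarely carry hydrogens, donor hydrogens are
reconstructed at ideal covalent geometry: 1.0 Å from the donor along the
direction pointing away from the mean of its bonded heavy atoms. This is a
single-H approximation (a backbone nitrogen uses only Cα as antecedent); a
heavy-atom-only mode skips angle checks entirely. Aromatic ring planes are
least-squares fits (SVD); tryptophan contributes both rings. Histidine is
cation-capable by default (configurable), matching the residue-class table.

Two disjointness conventions: atom pairs already recorded for a directional
interaction (hydrogen/S-Se bonds, salt bridges, chalcogen, C-bond, n→π*)
are not re-counted as van der Waals contacts; and an ARG–ARG pair whose
guanidinium groups stack is removed from the charge-clash category.
Clash vs repulsion uses minimum backbone-atom and minimum side-chain-atom
distances (centroid variants were the alternative; minimum distances make
the "backbones close, side chains apart" definition sharp for long side
chains). Glycine, having no side chain, is skipped with a warning.

## Region-resolved statistics

The residue classification follows the IMGT physicochemical scheme
(tyrosine: polar, neutral hydropathy). "Capability" — whether a residue
pair can chemically form a type — is explicit shipped data, e.g. only
ARG–ARG can arginine-stack and every pair is H-bond capable through its
backbone. The mean count per pair divides by all *capable candidate* pairs
in a region (≤ 14 Å), including non-interacting ones; candidate pairs
rather than all residue pairs are the denominator because pairs beyond the
candidate cutoff can never be observed interacting, and the statistic is a
conditional propensity. Binary types (salt bridge, stacking, the
clash/repulsion family, hydrophobic) get Wilson score intervals; counted
types get Student-t intervals.

Pair-vs-BSA scaling counts same-region pairs twice (once per chain side)
and merges rim with rim-NIS for that analysis only; region merging is
always per-analysis, never global. Stickiness uses the natural log and a
1e-6 pseudo-share on both fractions; a residue type absent from both areas
is reported missing, never zero.

Pair classes reduce residues to {positive, negative, polar, apolar}
(charged residues by charge, the rest by polarity), giving 10 unordered
pair classes. Entropy is in bits; evenness divides by log2(k) with k = 10
possible classes by default ("observed" mode available), and J is defined
as 1 in the degenerate k = 1 case. tf-idf uses raw total counts for tf and
the natural-log idf over structures; a type present in every structure has
idf = 0 and is removed at any positive threshold — a documented side
effect of the variant chosen. PMI frequencies entering the formula are
per-complex frequencies averaged over the complexes of a group
(mean-of-frequencies, not pooled counts); the heterogeneous branch carries
the factor 2 because an unordered heterogeneous pair arises two ways under
independence. PMI of an unobserved or filtered pair class is reported
missing, never −∞. Core and support are pooled for PMI robustness; interior
values always pool the whole dataset regardless of stability group.

Stability classification uses log10 of the affinity in molar units
(KD, IC50 or Ki taken as given); −6 and −9 are the transient/stable cuts
and boundary values fall into the intermediate band, since the definitions
are strict "above"/"below". Per-complex failures quarantine the complex and
are listed in a run report rather than aborting the manifest.

## Synthetic fixtures: what they emulate and what they do not

The fixture module generates every test input programmatically:

* **SASA toys** — up to three spheres with exact expected areas from the
  isolated-sphere and two-sphere cap formulas; placements creating triple
  overlaps are rejected because the closed forms stop applying.
* **Burial dimers** — isolated alanine probes surrounded by occluder-carbon
  shells; own-chain shells set the monomer rASA, partner-chain shells the
  complex rASA, so each probe's region label is known by construction. The
  rim-NIS band (0 < ΔrASA ≤ 5 %) is hit by a deterministic distance search
  for a single grazing occluder. Every generated fixture re-verifies its
  labels with the package's own SASA before being returned.
* **Interaction geometries** — idealized two-residue scaffolds per type;
  positives satisfy the criteria with a stated margin, negatives violate
  exactly one criterion (the distance, or the angle where one exists).
  Fixtures are detector-validated at build time, and distances are kept
  clear of *other* detectors' cutoffs so no secondary record flickers at
  machine precision.
* **Frequency tables** — residue classes drawn independently from a known
  distribution; pair classes from the independence baseline with selected
  cells multiplied by a coupling factor c, the added mass removed from
  cells sharing no class with the coupling. This keeps residue-class
  frequencies at their declared values, making the expected PMI of a
  coupled cell exactly log2(c). (Renormalizing the whole table instead
  would shift the expectation by the normalization constant.)

These fixtures exercise the rules, not biology: scaffolds are not folded
proteins, occluder shells are not packed cores, and pair draws are i.i.d.
rather than spatially correlated. Passing tests therefore demonstrate that
the implementation computes the stated definitions correctly — they say
nothing about how real interfaces are organized, which is what running the
pipeline on curated structures is for.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small inputs:
six-probe burial dimers (~1000 atoms), 50-residue random-walk chains for
the candidate filter, 1e5 draws for frequency recovery, a 400-complex
synthetic ensemble for the affinity regression. The ensemble's noise
(σ = 3.1 on log10 affinity) is chosen so the generating R² ≈ 0.09 matches
the scatter regime the regression is meant to operate in; the recovered
slope is then validated against its own 95 % confidence interval rather
than as a point match. Bootstrap intervals resample complexes (the unit of
replication) with a seeded generator, so fixed seeds give byte-identical
outputs; aggregate tables are written with fixed float formats for the same
reason.

## Known limitations

* Donor-hydrogen reconstruction is a one-H idealization; bifurcated
  hydrogen bonds and rotameric OH donors are approximated by a single
  direction.
* Aromatic subtype assignment uses the inter-plane angle only, without a
  lateral-offset criterion.
* The detectors' numeric defaults are declared, documented values — tuned
  for internal consistency with the fixture margins, not fitted to any
  survey of experimental geometries; every one is overridable.
* Biological assemblies are not generated from symmetry operators; the
  manifest must name the chain groups explicitly.
* Water-mediated bridges, nucleic-acid and ligand contacts, and any energy
  scoring are out of scope.
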