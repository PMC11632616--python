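# Methods

## Scope and model

A *water bridge* is a single crystallographic water hydrogen-bonded to at
least one amino acid and at least one ribonucleotide. The bridge is modeled
as a graph: residues and the water are nodes, hydrogen bonds are edges. The
topology label `A_a:w:N_n` counts unique amino acids (*a*) and
ribonucleotides (*n*) around the water; the multiplet order is
*a* + *n* + 1, equal to the water node's degree plus one. When any member
amino acid forms a direct hydrogen bond to a member ribonucleotide the
topology is cyclic (`cyc-` prefix); the prefix carries no sub-typing of
which bond closes the ring, because that refinement would multiply empty
classes without adding discriminating power.

Only the four canonical ribonucleotides (rA, rG, rC, rU) and the twenty
canonical amino acids participate. Modified residues, DNA, ligands and ions
are classified OTHER and ignored; protein–protein and RNA–RNA water bridges
are out of scope by definition of the interface. Multi-water chains (two or
more waters relaying a contact) are likewise out of scope: every bridge here
has exactly one central water, and one bridge is reported per bridging water
per retained model.

## Hydrogen-bond detection

Geometric criteria, with defaults donor–acceptor ≤ 3.35 Å, hydrogen–acceptor
≤ 2.7 Å, D–H–A angle ≥ 90° — a deliberately conservative distance envelope
that excludes serendipitous long contacts. Donor/acceptor role tables cover
water (O: both), the 20 amino acids (e.g. Arg NE/NH1/NH2 donors, Asp
OD1/OD2 acceptors, His ND1/NE2 both because protonation is ambiguous at
crystallographic resolution, Pro backbone N no donor, Cys SG both, Met SD
acceptor) and the 4 ribonucleotides (e.g. rA N6 donor and N1/N3/N7
acceptors, rG O6 acceptor, O2′ both, phosphate and ester oxygens
acceptors).

Two evaluation modes:

* `heavy_atom` (default): only the D–A distance is enforced. Deposited
  X-ray structures carry no hydrogens, and hydrogen placement for rotatable
  donors (water, hydroxyls, ammonium) is underdetermined, so a
  distance-only criterion treats all donors uniformly.
* `with_hydrogens`: donors with fixed sp2 geometry (side-chain amides,
  guanidinium, ring NH, nucleobase amino groups) receive idealized
  hydrogens (N–H 1.00 Å; ring NH on the external bisector of the two ring
  neighbors; amino-group H at ±120° in the sp2 plane) and the full
  three-criterion test. Rotatable donors still fall back to the D–A
  distance. The backbone amide H needs the preceding residue's carbonyl
  carbon; residues are treated independently, so backbone N also falls back
  to distance-only. This mode exists for sensitivity analysis, not as the
  default.

Water–water bonds are never enumerated (single-water bridges only), and
within-class (protein–protein, RNA–RNA) pairs are not emitted. Candidate
pairs come from a k-d tree; a brute-force all-pairs scan with the same role
tables serves as the test oracle. Loosening any criterion can only add
bonds (monotonicity), and detection is invariant to atom enumeration order.

As an alternative input path, HBPLUS `.hb2` fixed-width records can be
ingested and resolved against the parsed structure; unresolvable or
malformed records are skipped with warnings. Other HBPLUS parameters beyond
the three cutoffs are assumed to be at their defaults when comparing.

## Structure ingestion

gemmi reads PDB v3.x and mmCIF. Atom names are normalized across dialects
(`O2*`/`O2'`/`O2′` → `O2'`; `O1P` → `OP1`). One model is retained (model 1
by default — multi-model NMR files are outside the X-ray scope, but the
model is selectable). Alternate conformers resolve to the
highest-occupancy atom, ties to the lexicographically first altloc, so each
residue keeps one coherent geometry. Hydrogens in the input are dropped and
re-derived (or not) by the detector, for uniform treatment. Water residue
names default to {HOH, WAT, DOD, H2O} and only the water oxygen enters any
geometry.

Ribonucleotide moiety partition: phosphate = {P, OP1, OP2, OP3, O5′},
ribose = {O2′, O3′, O4′ and sugar carbons}, nucleobase = ring and exocyclic
base atoms. O3′ sits with the ribose because the O2′+O3′ combination
defines the ribose-mediated contact class; O5′ stays with the phosphate
ester it belongs to chemically. This partition shifts the Ph/Rb
percentages, so it lives in one table and is documented here. Amino-acid
chain parts: N, CA, C, O (and OXT) are main chain (m), every other polar
atom is side chain (s); Gly and Leu consequently have no H-bonding side
chain — the convention underlying the class arithmetic below.

## Edge assignment

Base-mediated contacts are assigned a nucleobase edge (WC, HG, SG):

1. **Two base atoms** bonded to the water: residue-aware pair tables, e.g.
   [N1, O6] → WC for rG, [N6, N7] → HG for rA, [O2, O2′] → SG for
   pyrimidines. The published pair lists mix purine and pyrimidine atom
   names; they are expanded per residue so lookups are unambiguous (the
   expansion is data, `data/edge_rules.tsv`, not code). A pair found in no
   table is left unclassified with a warning — the manual-review fallback.
   More than two base atoms on one water violates the geometric two-atom
   bound; the two closest to the water are kept, with a warning.
2. **One unambiguous atom**: purine N1 → WC, N7 → HG, N3 → SG, pyrimidine
   N3 → WC, and so on. rC N4 and rU O4 are treated as unambiguous WC: the
   HG pair list contains no pyrimidine entries, so the scheme never assigns
   HG to pyrimidines, leaving WC as their only edge in scope.
3. **One edge-shared atom** (rA N6, rG O6, rG N2, rC/rU O2): the Euclidean
   distance from the water oxygen to the two ring atoms adjacent to the
   contact atom decides. Strictly closer to the first-listed neighbor (the
   WC side for N6/O6/N2-vs-N1) selects that edge; otherwise — including the
   measure-zero tie — the second-listed edge. The ambiguous-atom table is a
   reconstruction from ring chemistry anchored on the rA N6 (N1 vs C5)
   rule; it ships in the same editable TSV so a revised table can be
   dropped in without code changes.
4. **O2′**: alone (without O3′) it carries SG-edge semantics while
   remaining a ribose atom for moiety statistics; together with O3′ the
   contact is ribose-sugar-mediated, not base-mediated.

Contacts spanning several moieties (e.g. base + phosphate) are annotated by
the dominant group, nucleobase > phosphate > ribose, and the multiplicity
is logged.

## Nomenclature

Names follow the grammar in the README. Ordering is canonical: on the
amino-acid side, main-chain (m) terms sit immediately left of `:w:`,
preceded by ms terms, preceded by side-chain (s) terms, names in descending
alphabetical order within each group; on the nucleotide side, base-mediated
terms come first (WC, then HG, then SG, nearest to `:w:` first), then
phosphate, then ribose, alphabetical within each group. Repeated identical
terms are rendered repeatedly, ordered by (chain, residue number) for
determinism. A residue contacting the water through both chain parts gets
portion ms. Parsing is the exact inverse on canonical names, with
positional error reporting.

**Theoretical classes** for nucleobase-mediated triplets: 4 bases × 3 edges
× (18 amino acids × 2 portions + 2 main-chain-only amino acids) = 456
single-portion classes, plus 4 × 3 × 18 = 216 ms classes, 672 in total —
identical for the acyclic and cyclic topology. The {Gly, Leu}
main-chain-only set is the survey convention, kept as an explicit constant
rather than derived from the role tables (chemically Ala, Val, Ile, Phe and
Pro also lack polar side chains, but the classification arithmetic is
defined over this convention).

## Survey statistics

The counting unit for residue-level tables is the hydrogen bond (one
water–residue-atom bond = one count); `unit="residues"` counts each bonded
residue once per water instead. Topology tables count bridges; B-factor
means weight each water oxygen once (bridging waters, all waters, and per
topology order). The amino-acid × ribonucleotide pair matrix counts
co-membership within a bridge, once per pair per bridge (the bond-pair
alternative is the documented flag). The triplet class table covers
A1:w:N1 and cyc-A1:w:N1 bridges whose nucleotide contact carries an edge
(WC/HG/SG, including the lone-O2′ SG case). Percentages print to one
decimal; unrounded values are kept internally so categorical tables sum to
100 ± 0.1. Waters with more than four hydrogen bonds exceed the
tetrahedral limit — usually positional ambiguity, occasionally bifurcated
bonds — and are flagged `over_tetrahedral`, never filtered. Report output
is deterministic: re-running on the same input gives byte-identical files.

One bridge is counted per bridging water; bridges are not deduplicated
across crystallographically identical chains.

## Synthetic fixtures

The generator realizes a declared inventory of bridges as a PDB file whose
expected pipeline output is fully determined by the manifest. Residues use
ideal heavy-atom geometry (the chemical component dictionary bundled with
biotite) and are placed rigidly around each water by a penalized
least-squares fit over rotation, translation and a few genuine internal
torsions (glycosidic χ for nucleotides; the carbonyl-O spin and side-chain
χ1 for amino acids — without them, contacts such as a water bridging O2 and
O2′, or a serine ms contact, are infeasible in the single ideal rotamer).

Margins make detection robust to coordinate rounding: intended bonds are
realized at ~2.85 Å (≥ 0.2 Å inside the cutoff, verified at ≤ 3.12 Å);
every unintended polar contact that could create a bond — any polar atom
vs. the water, and amino-acid vs. ribonucleotide polar pairs — is kept at
≥ 3.55 Å (≥ 0.2 Å outside the cutoff). Same-class polar proximity is not
constrained (it creates no detectable bonds and is common in real packed
structures); a general steric floor of 2.75 Å applies to everything else.
Distance-rule placements enforce the closer-than condition with a 0.4 Å
margin. Direct bonds for cyclic entries are restrained to 2.9 Å between a
role-compatible pair. Bridge sites sit on a 50 Å grid so sites cannot
interact. Placement uses Nelder-Mead multi-starts seeded per member from
the manifest seed; if greedy member placement corners itself the whole
entry retries with re-randomized sub-seeds, and a request that still cannot
meet the margins raises before anything is written. Same manifest, same
seed → byte-identical PDB.

The default ensemble (47 bridges) covers every observed topology (triplet
through quintet, acyclic and cyclic), every realizable two-atom pair rule,
both sectors of every distance-rule atom, the lone-O2′ and O2′+O3′ ribose
cases, ms portions, an over-tetrahedral water, plus non-bridging decoy
waters and within-class decoy motifs that must not become bridges. Edge
probes place a lone water at hydrogen-bond distance from one ambiguous atom
and slide it along the adjacent-atom axis; the expected edge is computed
analytically from the final coordinates by the same strictly-closer
comparison the classifier must make.

**What the fixtures do not emulate:** crystallographic noise, disorder,
alternate conformations in the same site, symmetry mates, chain copies,
modified residues, or realistic water networks (each fixture water touches
only its intended partners). Passing the recovery tests therefore
demonstrates that the pipeline's logic — detection, bridging, topology,
edges, names, aggregation — is exact on unambiguous geometry; it does not
certify behavior on degraded real-world data, where upstream choices
(altloc handling, occupancy, HBPLUS settings) dominate. Six-membered and
larger bridges are representable in the data model and nomenclature, but
the generator's clash-free realization is only exercised up to five
members around one water; beyond that the first hydration shell saturates
under the margins above.

## Numerical choices and degenerate inputs

* Distance-rule ties break to the second-listed edge (strict less-than).
* Waters lacking an O atom are classified OTHER at parse time.
* A structure with zero waters, or zero qualifying bonds, yields an empty
  inventory — not an error; empty reports keep their headers.
* Bond endpoints with `both` roles on both sides (e.g. water–O2′) are one
  bond with direction unrecorded.
* B-factor means over empty sets are NaN and serialize as null.
* Occupancy and B-factor are taken as deposited; only altloc resolution
  uses occupancy.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
fixtures: the 47-bridge default ensemble (~170 residues), 50 edge probes,
and sub-50-atom structures for the brute-force oracle. These sizes exercise
every code path; surveying real PDB datasets is a batch run of the same
per-structure pipeline over a user-supplied file list.
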