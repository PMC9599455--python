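# Methods

This note documents the models, numerical choices and limitations behind
`hcafold`, in the spirit of a methods appendix.

## Hydrophobic clusters and foldable segments

The cluster rule is implemented literally: two hydrophobic residues belong
to the same cluster iff fewer than four non-hydrophobic residues separate
them **and** no proline lies strictly between them; a proline therefore
splits a cluster regardless of gap length. The "plot" alphabet is
{V, I, L, M, F, Y, W}; segmentation mode adds C. Non-standard letters
(B, Z, U, O, and anything unknown) are normalised to X, which is never
hydrophobic and never proline. Coordinates are 1-based inclusive
throughout.

The "one or two consecutive hydrophobics" eligibility filter removes
exactly the patterns `1` and `11`; a multi-part pattern such as `1001`
survives, because its hydrophobics are not consecutive. Eligible clusters
whose inter-cluster linker is shorter than `linker_max` (default 10
residues, exposed as a parameter) merge into one foldable segment spanning
from the first to the last member cluster. The merge rule is this
package's own density criterion; it recovers planted cluster-dense blocks
with span Jaccard ≥ 0.9 on the synthetic benchmark and is deliberately
simple and tunable.

## The HCA score

The score is a per-residue log-odds between two fixed composition models:
a globular state in which a fraction p_g = 0.335 of residues are strong
hydrophobics organised in clusters (folded domains contain roughly one
third strong hydrophobics), and a disordered state with p_d = 0.15. With
f the Jeffreys-smoothed fraction of in-cluster hydrophobic residues over
the segment, f = (n_in_cluster + 0.5) / (L + 1),

    score = 10 · [ f · ln(p_g/p_d) + (1 − f) · ln((1 − p_g)/(1 − p_d)) ].

The scale of 10 maps the conventional soluble-domain window onto
[−1, 3.5]: the window bounds correspond to in-cluster hydrophobic
fractions of about 14 % and 57 %, so hydrophobic-poor (disordered)
segments fall below −1 and hydrophobic-rich (transmembrane-like) segments
rise above 3.5, which is the window's intended semantics. The score
depends only on residues inside the segment, is deterministic, and
increases strictly with cluster density at fixed length.

This scoring function is this package's own formulation. The historical
segment-scoring code it is inspired by uses empirical cluster-pattern
frequency tables; published per-segment values (e.g. a score of 0.62 for
the human SCARF1 cytoplasmic segment) are therefore not expected to be
reproduced digit-for-digit, although the window semantics and ordering
behaviour are designed to coincide. This is the package's main known
deviation from the historical toolchain.

## Confidence classes and thresholds

A segment is full-VL iff **every** residue has pLDDT ≤ 50 and full-VH iff
every residue has pLDDT > 90 — comparators are exact, with no epsilon;
pLDDT 50.0 is VL-side and 90.0 is not VH. The soluble-window bounds are
inclusive (−1 and 3.5 kept) while the length cutoff is strict (31 is the
shortest accepted segment).

Threshold calibration is order-statistic counting, not interpolation: the
upper bound for disorder/accessibility is the smallest observed value with
at least 95 % of full-VH segments at or below it; the lower bound for
homolog depth is the largest value with at least 95 % at or above it. On
10,000 i.i.d. draws this recovers the true 95th/5th percentiles within
twice the asymptotic quantile sampling error (verified in the acceptance
suite). An optional `decimals` argument rounds outward (up for upper
bounds, down for lower) so the coverage guarantee survives rounding; the
published one-decimal values (33.4 / 82.9 / 23.5) are available as a
separate `paper_defaults` mode so published tree leaves can be reproduced
without recalibration. Tie handling on tree edges follows the printed
comparators exactly: ≤ passes on the folded side for disorder and
accessibility, > passes for homolog depth, and the first split is RSS
presence (> 0 %) versus absence.

## Secondary structure

The Kabsch–Sander algorithm is implemented natively: the amide H is
reconstructed 1.01 Å from N along the C(i−1)→O(i−1) direction (no H for
chain starts, after breaks, or on proline); the electrostatic H-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol is
clamped at −9.9 for near contacts and a bond is called below −0.5;
helices G/H/I require two consecutive n-turns (n = 3, 4, 5); parallel and
antiparallel bridges (sequence separation ≥ 3) chain into ladders, with
single-bridge ladders labeled B and longer ones E; remaining turn
residues get T and CA-chain kinks above 70° get S. Priority is
H > E > B > G > I > T > S. Residues with an incomplete backbone are coil,
and a C(i)–N(i+1) distance above 2.5 Å is treated as a chain break.
Sheet-bulge extension and multi-sheet bookkeeping are not implemented;
the pipeline only consumes the {H,G,I,E,B} vs rest dichotomy, which
agrees with an independent DSSP implementation (mdtraj) on ≥ 90 % of
residues across mixed synthetic fixtures (100 % in the shipped runs).

## Solvent accessibility

ASA uses biotite's Shrake–Rupley implementation (probe 1.4 Å, 1000 sphere
points, heavy-atom radii) over all atoms present, summed per residue and
normalised by the Sander–Rost Gly-X-Gly maxima (X gets the 20-residue
mean, 167.5 Å²). Values may exceed 1 and are not clipped; a residue with
no atoms has no value and counts as inaccessible in coverage. The
extended Gly-X-Gly center sits at relative accessibility ≈ 1.0–1.1 under
this convention, and per-residue values are invariant under rigid motion
to within the sphere-sampling resolution (≲ 0.01).

## Synthetic data

The generator emulates the study conditions, not biophysics. Sequences:
helix blocks place hydrophobics on an i, i+3, i+4 heptad scaffold
(default density 3/7), strand blocks alternate hydrophobic/polar (1/2),
linkers are hydrophobic-poor with 12 % proline so no eligible cluster can
form. Structures: NeRF-built backbones from canonical bond geometry with
ideal helix (−57°, −47°) and strand (−139°, 135°) dihedrals; coils draw
random extended-region dihedrals, resampled until no two non-bonded atoms
within a coil's reach come closer than 2.5 Å (ideal-geometry block
junctions get a 2.0 Å floor instead, since resampling cannot move them).
A planted pLDDT level (constant or ramp) is written to the B-factor
column at two decimals. Disorder scores are sampled around the planted
level and clipped to the side of the 0.5 cutoff that level sits on, so
block coverage is exact by construction; alignments contain exactly the
planted number of ungapped rows per block. One integer seed drives
everything, and every generated file embeds it in a header line.

The default 50-protein study bundle places one foldable domain between
two disordered linkers per protein: half the domains are full-VH-like
(pLDDT 92–98, helical geometry, deep alignments), half full-VL-like
(pLDDT 30–48, shallow alignments), and 70 % of the VL domains keep a
foldable sequence but receive random-coil model geometry — the
foldable-but-unfolded situation the taxonomy exists to expose. Domain
lengths (45–80 for VL, 68–130 for VH) were chosen to reproduce the
published mean segment lengths (≈ 61 vs ≈ 92 residues). At this scale a
run produces ~50 segments; this keeps the full test suite under a minute
while exercising every leaf family of both trees.

What passing on this generator does **not** show: real disorder has
heterogeneous composition and transient structure, real models have side
chains and imperfect geometry (accessibility here is driven by
backbone+CB atoms only), and real alignments have gradual, not blockwise,
coverage. The generator validates the machinery — delineation, feature
extraction, calibration, routing, accounting — not biological effect
sizes.

## Scale of the shipped verification runs

The acceptance battery uses 10,000 random sequences for the delineation
oracle, a 50-protein bundle for end-to-end recovery, 50 mixed-topology
fixtures for the secondary-structure cross-check, and 10,000 draws for
calibration recovery; these sizes give exact or tightly-bounded checks in
well under a minute on a single CPU.

## Known limitations

- The HCA score is a parametric stand-in with matching window semantics,
  not a port of the historical table-based scorer (see above).
- mmCIF models, multi-chain complexes and AFDB fragment stitching are out
  of scope; one model file is one independent single-chain entry.
- β-bulges and sheet topology bookkeeping are omitted from the secondary
  structure assignment (irrelevant to the RSS dichotomy consumed here).
- Disorder and alignment tools (IUPred2, jackhmmer) are not re-implemented;
  their file outputs are the interface. For producing real inputs the
  conventional search settings are an e-value of 1e-4 and one iteration
  against the reduced BFD.
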