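# Methods

## The algebra

The alphabet {E, C, A, T/U, G} is identified with Z/5 through the phase
index m (E=0, C=1, A=2, T=3, G=4); RNA differs only in rendering m=3 as U,
never in arithmetic. The five shifts n, r, u, d, l are stored canonically
as r-exponents k ∈ Z/5 (u = r², d = r³, l = r⁴); the rotational aliases
ω_k and wallpaper pairs x[a,b] are parse/print forms only, which removes
any chance of representation drift between the three notations. The
wallpaper composition x[a₁,b₁]·x[a₂,b₂] = x[a₁+a₂, b₁+b₂] and the canonical
exponent (a+2b) mod 5 are consistent by construction; the five in-cell
(a,b) pairs per element are available from `xy_pairs`. The u-power form of
a base index m uses the forced identity u^k = r^(2k), so the u-exponent
realizing m is (3m) mod 5 — the only version the algebra admits.

## Sequence vectors and E bookkeeping

A SeqVector is a sparse map place → index with 1-based places. An explicit
E (stored 0) is distinct from an implicit E (absent place): the former is
tracked through edits and deletable, the latter is background. The infinite
trailing tail of E's is notational and never stored; explicit text rendering
appends a `|E...` marker. `braces` (the { } transform) demotes explicit E's
to implicit without renumbering; `angle` (the ⟨ ⟩ transform) deletes them
and renumbers 1..N. `length_N` counts explicit non-E entries and is
invariant under all bookkeeping transforms, as is the conventional (plain
letter) text. `reverse` acts on the span 1..max-explicit-place, mapping
implicit gaps symmetrically, and flips the 5′→3′/3′→5′ label — the minimal
extension of the dense finite case. Sequence equality is label-sensitive
(alphabet and direction) by default; `same_bases` compares base content
over the union of supports with explicit E ≡ implicit E, which is the right
notion after operator application.

## Operator vectors

An OpVector stores only non-identity components (exponents 1–4);
composition and inverse are componentwise, so the group laws reduce to the
component algebra, which is finite and checked exhaustively. Application
may act at implicit places (materializing an explicit base from the E
background) and keeps a base erased to E as an explicit E, since later
deletion steps depend on tracking it. `diff` is strictly positional — it
never aligns; indel bookkeeping is done first with insert_E/delete_E, as in
the two-step insertion idiom. Operators carry no direction label and act in
the coordinate frame of their target.

## Recombination

To swap segment c (places f_c..l_c) of one sequence with segment d
(f_d..l_d) of another: pad with |d| explicit E's immediately *before* the
segment in the first sequence and |c| E's immediately *after* the segment
in the second (the deliberate asymmetry reproduces the defining procedure
and is what makes the operator pairing below exact); then one operator per
sequence writes the partner's segment into the fresh E block and erases
the native segment to E's. The two operators have componentwise-inverse
edit patterns; as stored vectors `inverse_op(op_c) == op_d` exactly when
f_c = f_d (true in the canonical worked example), and in general after
re-anchoring by the offset f_d − f_c (`OpVector.shift`). Both forms are
tested. Length-0 segments and segments beyond the explicit span are
rejected rather than guessed at. Base content (the multiset of real
letters across both sequences) is conserved.

## Central dogma pipeline

complement → transcribe (alphabet relabel; a morphism between different
objects, hence not a group element) → splice (intron intervals, inclusive
1-based in the transcript's own place numbers, become explicit E's; place
numbers unchanged) → mature (= the ⟨ ⟩ transform; the only renumbering
step). The complement step is on by default and can be disabled
(`complement=False`) to transcribe the given strand directly — both
readings of the transcription convention are supported, the default
following the worked chain. Codon partition groups the conventional
letters in threes after skipping `frame` leading letters, the skipped
letters forming their own group; it requires a matured vector (explicit
interior E's are an error, trailing ones are fine).

## Category and functor checks

Morphisms: f and h are operator vectors on DNA/RNA objects, ρ is the
complement, τ the DNA→RNA relabel, g = ρ then τ, and j a splice-interval
set. τ and g change the object and are relabel steps, never OpVectors; h is
typed Z→Z. Laws are checked by evaluation, not symbolic proof:
exhaustively over all 25/125 component pairs/triples (the component algebra
is finite, so exhaustiveness is decisive) and on seeded sample sequences at
the vector level. The functor into the rotational representation maps
aliases r→ω₁, u→ω₂, d→ω₃, l→ω₄, n→ω₀ with exponents unchanged; a
`component_map` hook exists solely to demonstrate that a corrupted mapping
is detected (negative control).

## Grid and charts

The grid window is generated by cell(x,y) = (origin + x + 2y) mod 5 with
(x right, y up) and signed coordinates permitted; this single modular rule
implies the row cycle E-C-A-T-G, the A-above-E alignment, the knight's-move
tiling, and the central complement symmetry cell(−x,−y) = cell(x,y)†.
Sequence charts plot one point per explicit entry at (place, index) with
E = 0 — a deterministic, information-preserving charting convention — with an
optional flag to plot implicit E's (default off) and an SVG polyline export
with the five index levels labeled.

## I/O conventions

FASTA (via Biopython) writes E inline as a literal letter, because E takes
part in the group arithmetic and is not an alignment gap; `-` ↔ E
conversion flags exist for interop. Record descriptions carry
`alphabet=`/`direction=` tags; on read the alphabet is otherwise inferred
(U ⇒ RNA, T ⇒ DNA, neither ⇒ DNA), and mixing T and U in one record is an
error. The evec and editlog JSON sidecars are serialized canonically
(ascending places, fixed separators) so round-trips are byte-exact.

## Randomized fixtures and what passing shows

The fixture generator draws letters uniformly over the four real bases and
makes each position an explicit E independently with probability
`p_explicit_E` (property suites use 0.2, a density that exercises both
explicit-E tracking and the implicit background without degenerating into
mostly-gap vectors). All randomness is seed-driven and reproducible.
Random vectors of length ≤ ~25 with i.i.d. letters are ample for the
algebraic laws verified here — the laws are position-local and
length-independent — but they emulate no biological sequence composition
(GC content, repeats, motif structure), so passing says nothing about
biological plausibility, only about the correctness of the algebra and
bookkeeping. Property suites run 1000 seeded cases per law in the
acceptance tests (fewer, via hypothesis, in the unit suites); the aggregate
self-check uses 100–200 samples, sizes at which every suite completes in
seconds.

## Known limitations

Codon→amino-acid translation, reverse transcription, stop-codon semantics,
splice-signal detection, and double-stranded pairing constraints are out of
scope. `diff` is positional, not an alignment algorithm. The strict
stored-vector form of the recombination inverse identity requires equal
segment start places (see above). Only the canonical letter arrangement of
the grid is built; alternative base permutations would yield an isomorphic
model.
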