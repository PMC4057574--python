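# basefive

A library and CLI that treats DNA/RNA sequence editing — substitution,
insertion, deletion, recombination, and the complement → transcription →
splicing → maturation chain — as actions of a single Abelian group over a
five-letter alphabet.

## The model

The four nucleotide letters are extended with a fifth, "empty" base **E**,
giving the set {E, C, A, T/U, G}. Each base carries a phase index
m ∈ {0..4} (E=0, C=1, A=2, T/U=3, G=4), equivalently a fifth root of unity
Exp(m·2πi/5). The five shift operations on this alphabet —
**n** (stay), **r**, **u**, **d**, **l** — form the cyclic group
Z₅ = ⟨r⟩ with u = r², d = r³, l = r⁴; a shift with exponent k sends index m
to (m + k) mod 5. Three equivalent notations are supported: linear r^k,
rotational ω_k ("w0".."w4"), and wallpaper displacements x[a,b] = r^a·u^b
with canonical exponent (a + 2b) mod 5. The same rule generates a wallpaper
grid from a cruciform motif (C right of E, A above, T below, G left),
tiled by a knight's-move translation, on which every row cycles E-C-A-T-G.

A sequence is a **SeqVector**: a sparse map from 1-based place numbers to
explicit bases over an implicit infinite background of E's. Because E is a
first-class base, an insertion is "insert tracked E's and shift place
numbers", a deletion is its inverse, and writing or erasing a base is a
substitution to/from E. An **OpVector** is a componentwise tuple of Z₅
shifts acting place-by-place (D_j ∘ B_{j→k} = D_k); these vectors form an
Abelian group, `diff` recovers the unique operator between two aligned
sequences, and the complement is realized per component by the shift
(−2m) mod 5, giving A↔T/U, C↔G, E↔E.

On top of the algebra sit: generalized edit scripts (substitute + E
insertion/deletion with full inversion), segment **recombination** between
two sequences via complementary E-padding and a pair of componentwise-
inverse operators, and the central-dogma pipeline complement → T→U relabel →
intron-to-E splicing → maturation (the ⟨ ⟩ transform that deletes explicit
E's and renumbers), ending in codon partition of the mature mRNA. A
category-law checker verifies identity/associativity of the morphism chain
and the functor into the rotational (phasor) representation.

## Worked example

```sh
$ printf '>template\nTCATEAGCTGA\n' > t.fasta
$ basefive dogma --introns 2:4 --frame 0 t.fasta
AUCGACU
AUC|GAC|U
```

The template strand `TCATEAGCTGA` (the E marks a tracked gap) is
complemented to `AGTAETCGACT`, relabeled as RNA `AGUAEUCGACU`, the intron
at transcript places 2–4 (`GUA`) is replaced by explicit E's, and
maturation deletes all non-trailing E's and renumbers — the mature mRNA is
`AUCGACU`, read in frame 0 as the codons `AUC|GAC|U`.

Recombination swaps a segment between two sequences and reports the padded
explicit vectors (place numbers included, `|E...` marking the implicit
tail):

```sh
$ basefive recombine c.fasta d.fasta --seg-c 3:6 --seg-d 3:7
G1 E2 A3 G4 C5 T6 A7 E8 E9 E10 E11 |E...
A1 T2 E3 E4 E5 E6 E7 T8 A9 G10 T11 |E...
```

for `GETAGT` (segment 3–6) and `ATAGCTA` (segment 3–7): each sequence now
carries the other's segment, the erased bases remain as tracked E's, and
the two substitution operators that realize the swap are componentwise
inverses of each other.

Other verbs: `complement`, `transcribe`, `splice`, `mature`, `diff`,
`apply`, `edit` (JSON edit scripts), `grid` (the wallpaper window),
`orbit` (polyline chart of a sequence, optionally SVG), `selfcheck`
(exhaustive component-level group/category laws plus seeded property
suites), and `fixtures` (seeded random sequences). Sequences are FASTA or
the `evec` JSON sidecar (explicit vector with place numbers); operators use
the `editlog` JSON format.

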