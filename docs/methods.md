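# Methods

## The assay being modelled

A transposon-display library targets one retrotransposon family at a time.
Genomic DNA is randomly fragmented; forked adaptors are ligated; PCR with a
family-terminus primer and an adaptor primer amplifies only fragments that
contain the element's end adjacent to flanking genome; products are
size-selected to 500–1,000 bp and sequenced as 150 bp paired-end reads.
Read 1 therefore always begins at the family primer, crosses the junction
and runs into unique flanking genome. After preprocessing, the first 50 bp
of flank is the unit of analysis: near-identical 50-mers are one insertion
site; the site's read count per cultivar, relative to that cultivar's total,
yields a presence/absence genotype; rows with a single presence are
cultivar-specific markers.

## Synthetic panel generator

`tipprof.simulate` emulates exactly this design, and its defaults are the
study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `size_select_min/max` | 500 / 1,000 bp | gel size-selection window of the library |
| `read_length` | 150 bp | paired-end read length |
| `depth` | 100 | mean reads per (site, cultivar), Poisson-distributed |
| `base_error_rate` | 0.005 | per-base substitution probability |
| `quality_mean/sd` | 35 / 3 | per-base Phred model (clipped to [2, 41]) |
| `fragment_mean/sd` | 700 / 150 bp | shearing model behind size selection |
| `min_flank_edit_distance` | 10 | distinctness floor between site flanks |

Site placement: all cultivar genomes derive from one random backbone, and
every site keeps ≥ 2 x `size_select_max` from its neighbours, so no fragment
can span two insertions and a site's informative flank is identical in every
carrier. Shared sites are carried by a random subset of ≥ 2 cultivars;
specific sites by exactly one (`n_specific_sites_per_cultivar`, per family).
Flank distinctness is enforced at generation by redrawing coordinates until
all pairwise 50-mer edit distances are ≥ 10 (computed with edlib); in
practice random flanks are far more distant, and the floor only rejects
pathological draws. An amplicon's length is the distance from the terminus
primer to a random downstream shear point (normal fragment length, junction
uniform within the fragment), rejected outside the size window. Reads get
iid substitution errors and iid Phred values.

Randomness is a documented hierarchy of numpy `SeedSequence` streams: the
population stream (`[seed, 0]`) draws backbone → site coordinates →
presence patterns; each (cultivar, family) library stream
(`[seed, 1, cultivar_idx, family_idx]`) draws per-site Poisson counts, then
per-read geometry, errors and qualities. Identical seeds give bit-identical
FASTA/FASTQ output, and a library's total read count can be re-derived
independently from the stream contract.

What the generator deliberately does **not** model: indel errors, quality
decay along the read (qualities are iid, so in simulation virtually no read
fails the QV filters, unlike real libraries where the two QV stages remove
half the reads), PCR duplicates beyond the uniform depth model, barcode and
nested-PCR structure (reads are emitted demultiplexed), chimeric fragments,
heterozygosity (calls are haploid presence/absence) and terminus truncation
variants. Passing tests therefore demonstrate correctness of the analysis
logic under the assay's idealised geometry, not robustness to every failure
mode of real sequencing.

## Preprocessing

Four stages, in the order the stage report lists them:

1. *Adaptor removal and QV filtering.* The configured family terminus is
   stripped from the 5′ end when it matches within 20% mismatches — the
   terminus is the synthesized primer, present by construction, and an
   untrimmed prefix would shift the junction 50-mer and fabricate a phantom
   site, so the tolerance is deliberately generous. The 3′ adaptor is
   removed at the leftmost suffix matching an adaptor prefix with ≥ 5 bases
   overlap and ≤ 10% mismatches. A read survives if its mean Phred is ≥ 30.
2. *Truncation to 50 bp*; shorter reads are dropped.
3. *A second mean-QV ≥ 30 filter* on the 50-mer. QV filtering is
   interpreted as mean-per-read (the mode is configurable in principle;
   per-base and windowed variants were considered and rejected as
   under-determined), and it appears twice because the stage layout lists
   two QV passes around the length trim.
4. *Outlier filtering*: groups of ≥ 10 identical 50-mers collapse to one
   representative; smaller groups pass through complete. This is the only
   order-changing stage (output sorted by sequence, for byte-reproducible
   results).

Stage ratios are percentages of raw reads, rounded half-up to 2 decimals.
Only read 1 enters the cascade; read 2 exists to confirm library structure.

## Clustering

A deliberate re-implementation of tiled seed-and-extend self-alignment
(the published parameterisation of the BLAT program it emulates: tileSize 8,
minMatch 1, minScore 10, repMatch −1 i.e. no tile masking, oneOff 2).
Semantics chosen where the parameterisation under-determines them:

- seeds are non-overlapping 8-mer tiles on both sequences; a seed pair
  counts when the tiles differ at ≤ `one_off` positions and their offsets
  differ by ≤ 10 (the alignment shift bound). `oneOff = 2` exceeds the
  aligner's documented range, so it is exposed as a plain
  mismatches-per-tile parameter honouring the printed value;
- extension is ungapped (junction reads share the terminus anchor; gaps are
  not part of the model): score = matches − mismatches of the best offset
  alignment within ±10; linked iff ≥ `min_match` seed pairs *and*
  score ≥ `min_score`;
- pairwise links become clusters by single linkage (connected components,
  union-find). Representative = highest-multiplicity member, ties to the
  lexicographically smallest; per-cultivar counts re-attach the
  *pre-collapse* multiplicities of all members.

The implementation finds candidate pairs through a tile index queried via
the ≤ 2-mismatch neighbourhood of each tile (277 neighbours per 8-mer) and
is checked in the tests against an independent all-pairs oracle (vectorised
scoring + scipy connected components) on instances of up to 200 reads.
The partition is input-order invariant.

## Genotyping and screening

`calls[s, c] = 1` iff `counts[s, c] / totals[c] ≥ 0.001`. The boundary is
part of the rule: absence is declared strictly below 0.1%, so exactly 0.1%
calls presence; the comparison is done on the read-share ratio so
999/1,000,000 → 0 and 1,000/1,000,000 → 1 exactly. The denominator
`totals[c]` defaults to the cultivar's read count after the second QV
filter — the last stage at which reads still count with multiplicity, hence
exactly the reads that can appear in cluster counts (this keeps
`counts ≤ totals` invariant); a raw-read denominator is available as a
config choice. Sites called absent everywhere are dropped before screening.
A marker candidate is a site whose call row is 1 at the target cultivar
only; the specificity summary counts unique sites per cultivar x family.

## Marker validation

Virtual PCR is mismatch-bounded string matching: a primer site requires
≤ `max_mismatch` mismatches *and* an exact 3′-terminal base (polymerase
extension is 3′-intolerant); both strands are scanned and products are
reported with 0-based half-open forward-strand coordinates when their length
falls in the pair's product range. Thermodynamics (Tm, annealing
temperature, cycling, yield) is out of scope — the testable claim of a
junction marker is the existence of a priming-site pair, not reaction
kinetics. LAMP validation is likewise purely structural: FIP must decompose
as F1c+F2 and BIP as B1c+B2 against the target (split search with both
halves ≥ 15 bases), regions must be ordered F3 < F2 < F1 < B1 < B2 < B3,
loop primers (optional — junction targets often only admit LoopB) must fall
inside their loops, and unmapped elements are reported, not raised.
Lateral-flow tag/biotin labels are metadata, checked only for the duplex
rule (one tag, one biotin per set).

## Problem sizes in the shipped analyses and tests

The bundled 24-cultivar grape panel tables (three families; totals
94,648,193 / 86,034,789 / 149,157,571 reads) exercise the summary
arithmetic exactly. The synthetic study uses 6 cultivars x 3 families with
30 sites per family — each cultivar privately carrying 4 VINE1-, 2 Gret1-
and 1 Tvv1-specific sites, mirroring the structure of a real
target-cultivar screen — at depth 100 and 0.5% error (~23,000 read pairs),
a size chosen so a full run completes in seconds while every downstream
property (one cluster per site, 100% call concordance, exact unique-site
recovery, virtual-PCR specificity) is still sharply falsifiable.
Archived-scale sequencing runs (tens of millions of reads per family, with
their hundreds of clusters and their specific-site tallies) are not
reproduced here: they require the original data deposits, and the synthetic
studies above stand in for them as correctness evidence.

## Known limitations

- Single-linkage clustering can, in principle, chain distinct sites through
  intermediate sequences; the simulator's flank-distinctness floor and the
  `min_score` bound make this vanishingly unlikely in the tested regime,
  but highly repetitive flanks in real genomes would need the (disabled)
  tile-abundance masking.
- The 0.1% rule has no statistical error model; calls near the boundary
  carry no confidence measure.
- Virtual PCR ignores primer thermodynamics and secondary structure, so an
  in-silico-specific marker still needs wet-lab confirmation.
- The LAMP validator checks architecture against a supplied target; it does
  not design primers.
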