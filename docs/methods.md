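# Methods

## The identification model

A transcription factor is operationally defined here as a protein whose
evidence bundle satisfies a family-assignment rule: a set of required
DNA-binding-domain (DBD) accessions (each with a minimum number of
distinct, non-overlapping copies), an optional forbidden set, and an
integer priority. Classification is a pure function of the evidence
bundle and the rule set; among matching rules the highest priority wins,
with specific multi-domain and copy-number rules ranked above
superfamily catch-alls. Proteins matching no rule are reported as
`unclassified` rather than dropped, so misses are visible.

Evidence enters through three channels with different strengths:
similarity search against a TF database recovers divergent homologs even
when domain models miss them; domain annotation from member databases is
precise but plant-biased; custom profile HMMs cover twelve DBDs absent
from the member databases. A protein whose only evidence is a best BLAST
hit inherits the family encoded in the subject id of the matched
database entry (subjects follow the `family_slug|entry` convention);
`--require-dbd` disables this fallback for users who want domain-level
support for every call.

## Filtering thresholds

| Threshold | Default | Why |
|---|---|---|
| BLAST max e-value | 1e-10 | similarity-search significance floor |
| BLAST min identity | 35 % | below this, TF family identity is unreliable |
| BLAST min alignment length | 100 residues | excludes short local matches to isolated motifs |
| annotation max e-value | 1e-3 | domain-annotation significance floor |
| profile-HMM policy | per-profile score cutoffs | mirrors curated gathering thresholds |
| profile-HMM fallback e-value | 1e-5 | profiles without a stated cutoff |

All comparisons are inclusive. The custom ALG_* profiles carry score
cutoffs of 22 bits in the bundled rules file; these are data, settable
per profile. Best-hit ties break deterministically (bit score, then
e-value, then subject id) so reruns are byte-identical.

## Curation heuristics

**MYB.** The annotation e-value filter produces false negatives for MYB
repeats, so MYB-domain evidence re-enters unfiltered on a flagged path
(`myb_relaxed_path`). The number r of non-overlapping MYB repeats maps
to MYB (3R) (r ≥ 3), MYB (2R) (r = 2) or MYB-related (r = 1);
single-repeat proteins whose repeat subsequence matches the SHAQKYF
recognition-helix pattern (`SH[AL]QK[YF]`, configurable in the rules
file) become MYB-SHAQKYF. No motif definition for the SHAQKYF class is
standardized; this pattern encodes the class-naming residues with the
two commonly observed substitutions and is deliberately exposed as data.

**G2-like cross-annotation.** The G2-like DBD closely resembles the
SHAQKYF-type MYB domain. Every protein carrying both a G2-like profile
hit and a SHAQKYF call is flagged and re-scored: the higher profile bit
score decides the family.

**Copy counting.** Non-overlapping copies are selected greedily by
ascending start coordinate; an instance overlapping an already selected
one by more than 50 % of the shorter length is treated as the same copy.
Greedy selection is deterministic and order-independent; it can
undercount relative to a maximum-independent-set optimum only in
adversarial nested layouts that do not occur with real domain
annotations (the tests bound it by an exhaustive oracle).

## Benchmarking

Per family: TP (predicted ∩ gold), FP (predicted − gold), FN (gold −
predicted); sensitivity = TP/(TP+FN), PPV = TP/(TP+FP). Undefined
ratios (zero denominators) render as `NA`, never 0 or 1, to keep summary
statistics honest. Display convention: ratios truncate at two decimals
(a sensitivity or PPV below 1 never prints as 1), while table
proportions round half-up at two decimals; raw values are retained in
machine output.

## Comparative layer

The substrate is a species × family count table; a published
seven-microalga table is bundled as the worked example. Conventions:

* **Proportions** are 100·count/total per species. `algal_totals()`
  carries the totals the source publication states and normalizes by;
  for *P. purpureum* that total (199) exceeds the sum of the broken-out
  family rows by one — an inconsistency internal to the source table —
  so reproducing the published percentages requires the published
  denominator. The default path uses row sums.
* **Presence/absence** is computed at family level: the two AP2/ERF
  subfamily rows collapse into one family column, while MYB classes,
  NF-Y subunits and the Homeobox/C2C2/GARP rows count as separate
  families. Under this convention the published per-species family
  counts are recovered for five of the seven species exactly (including
  the 37 families of *C. reinhardtii*); the remaining two differ by one,
  consistent with counting slips in the source.
* **Species dendrogram**: Euclidean distance on the 0/1 rows with
  complete linkage — the conventional hierarchical-clustering defaults —
  exported as Newick with branch lengths from merge heights. Both metric
  and linkage are configurable because the choice is convention;
  topology-level properties, not branch lengths, are the supported
  claims.
* **Family clustering**: the same defaults on raw (unscaled) proportion
  profiles, cut at k = 4 clusters; row scaling is available by flag.
* **SHAQKYF ratio**: 100·SHAQKYF/(SHAQKYF + MYB-rel), the union
  denominator. Published per-species values for this statistic are not
  all consistent with any single denominator convention; the union
  convention matches the three stramenopile/rhodophyte values exactly
  and is used throughout.

## Synthetic fixtures

The generator emulates the study conditions at desk scale: proteins are
uniform-random amino-acid sequences (background) with fixed, recognizable
placeholder subsequences at planted domain coordinates; each planted
protein carries exactly its family rule's minimal architecture. Evidence
is written to real files in all three dialects so parsers and filters are
always in the loop. The default panel spans twelve families chosen to
exercise every special path (copy numbers, subfamilies, custom profiles,
the MYB/SHAQKYF/G2-like curation chain); the default closure fixture is
5 proteins per family (60 proteins), and the noise fixture 10 per family
plus decoys — sizes at which every planted case is covered and the whole
suite runs in seconds.

Noise semantics: `fn_rate` drops each planted domain instance
independently; a protein losing all domains also loses its BLAST hit
(the same divergent sequences defeat both searches), surfacing as a
false negative. `fp_rate` has two faces: spurious hits on true proteins
are written with non-significant e-values or non-DBD accessions and must
be removed by the filters, while convincing false positives are planted
as decoy proteins carrying a full family architecture but absent from
the gold standard. Spurious hits never use MYB accessions, because the
relaxed MYB path bypasses the e-value filter by design (the original
protocol resolved this with manual inspection, which has no automatic
counterpart). The generator records every drop and decoy, so expected
post-noise assignments are recomputable from the planted record alone —
the account the pipeline output is tested against.

What the fixtures do not emulate: sequence evolution, homologous but
non-identical domain instances, overlapping annotations from multiple
member databases, partial-domain matches, and realistic e-value/score
distributions. Passing tests therefore demonstrate the correctness of
the plumbing, filtering logic, rule engine and arithmetic — not scanner
sensitivity on real proteomes.

## Degenerate inputs and determinism

Empty evidence files yield empty (valid) results; duplicate FASTA ids,
evidence for unknown proteins, rule files with duplicate families or
priority ties, zero species totals and sub-2 species dendrograms are
hard errors naming the offender. Every pipeline stage is deterministic;
all randomness in the fixture generator flows from explicit integer
seeds.

## Known limitations

* The bundled rules file is a reconstruction of catalogue family
  definitions, not a published artifact; accession lists are
  replaceable data.
* InterProScan input is assumed to be the TSV dialect; XML dialects are
  out of scope.
* BLAST-only family inheritance depends on the subject-id naming
  convention of the TF database used.
* Overlap resolution between member databases reporting the same domain
  is limited to the 50 % copy-counting rule.
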