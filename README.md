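# egt-screen

Phylogenetically informed screening of proteomes for nuclear pore complex
(NPC) protein families, built to answer a specific comparative-genomics
question: when a cell carries a **nucleomorph** — the relict nucleus of a
eukaryotic endosymbiont, as in chlorarachniophyte and cryptophycean algae —
does that second nucleus still have its own NPC?  Three genomic signatures
distinguish the possibilities: nucleoporin genes transferred from the
endosymbiont to the host nucleus would show **algal phylogenetic affinity**
and carry the **signal peptide** that starts the nucleomorph-targeting
presequence; dual-targeted host nucleoporins would show host affinity plus a
signal peptide; complete loss would leave only single-copy, host-related,
signal-peptide-free genes.

The package is aimed at molecular evolution researchers who have per-taxon
protein FASTA files (e.g., translated transcriptome assemblies), curated
reference alignments for the protein families of interest, and a table
assigning each taxon a role: `query_host_lineage` (the nucleomorph-bearing
lineage under study), `host_outgroup`, `endosymbiont_algal`, or
`other_reference`.

## The method

1. **Profile-HMM search** (`profile_hmm`, `homology_search`).  For each
   family, a match/insert/delete profile HMM is estimated from the reference
   alignment (columns with gap fraction < 0.5 become match states;
   background-proportional pseudocounts; Laplace-smoothed transitions).
   Every proteome is scored with local Viterbi; significance comes from a
   Gumbel extreme-value calibration fitted to background decoys, and hits
   are kept at E ≤ 10⁻⁵ with the best 200 hits per family retained.
   Each hit protein is assigned the family whose profile gives it the
   highest forward bit score, with the margin to the runner-up.
2. **Tree building** (`phylo`).  Retained hits are inserted into the
   reference alignment via their Viterbi path; per-family gene trees are
   inferred by neighbor joining on Kimura-corrected protein distances with
   nonparametric bootstrap supports (default 100 replicates) and rooted at
   the midpoint.  Externally computed trees (e.g., maximum likelihood) can
   be imported as Newick.
3. **Paralog purge and provenance calls** (`provenance`).  Over up to three
   realign-and-rebuild cycles, well-supported clades dominated by a
   different family assignment are removed.  Each query protein is then
   classified by its sister clade: **host_related** or **algal_related**
   when the reference leaves joining it are ≥ 80% of the corresponding role
   *and* the joining node's bootstrap support is strictly above 70;
   otherwise **ambiguous** (or **unclassifiable** with no references).
4. **Targeting evidence** (`targeting`).  A transparent signal-peptide
   heuristic (n-region charge, hydrophobic core, small-residue cleavage
   motif) that refuses a verdict on proteins with incomplete N-termini
   (checked against aligned reference methionines or upstream ORF-caller
   metadata), plus an FG-dipeptide repeat scanner for central-channel
   nucleoporins.  External predictor output can be imported.
5. **Inventory** (`inventory`).  Everything is summarized as a family ×
   taxon matrix of copy counts, affinities, SP and N-terminus flags, with a
   control-family completeness proxy, corroboration of absences shared by
   several sufficiently complete taxa, and an NPC subcomplex presence
   summary for the host and (algal-derived) nucleomorph complements.

A seeded synthetic-data generator (`synthetic_data`) builds ground-truth
scenarios — species tree, family evolution, endosymbiotic gene transfer
with SP gain, losses, duplications, decoy paralog families, truncation —
so the entire chain is validated against a truth table at desk scale.

## Worked example

Simulate a small ground-truth scenario (4 families across 14 taxa, with
algal-derived, signal-peptide-bearing extra copies of Nup98 and Rae1 planted
in every query taxon) and run the full screen:

```bash
echo '{"families": ["Nup98", "Rae1", "Sec13", "Nup62"],
       "length_range": [200, 300],
       "n_query": 4, "n_host_outgroup": 3, "n_algal": 4, "n_other": 3}' \
  > scenario.json
egt-screen simulate --seed 7 --out bundle --config scenario.json
egt-screen run-all --bundle bundle --out out --seed 7
# screen complete: 64 hits, 24 affinity calls; outputs in out
```

`out/calls.tsv` holds one provenance call per query protein:

```
family  protein           taxon   label          support  sister_roles           retained
Nup62   query1_Nup62_h1   query1  host_related   100      host_outgroup:3        1
Nup98   query1_Nup98_nm1  query1  algal_related  100      endosymbiont_algal:4   1
```

The host-derived Nup62 copy clusters with the three host outgroups; the
planted Nup98 transfer clusters with the four algal references — both at
bootstrap support 100, so both calls are confident.  `out/matrix.tsv` shows
the copy structure per (family, taxon) cell:

```
family  taxon   copy  protein            affinity       sp  nterm  copy_count
Nup98   query1  1     query1_Nup98_h1    host_related   0   1      2
Nup98   query1  2     query1_Nup98_nm1   algal_related  1   1      2
Sec13   query1  1     query1_Sec13_h1    host_related   0   1      1
```

Nup98 is two-copy with exactly one algal-related, signal-peptide-positive
(`sp` = 1) copy — the genomic signature of a nucleomorph-retained gene —
while Sec13 is single-copy host-related, the signature of NPC loss.  The
subcomplex summary aggregates this: the `nucleomorph` group is colored in
only for the subcomplexes that the algal-related families belong to
(central channel for Nup98, cytoplasmic complex for Rae1), while the `host`
group covers every subcomplex with any family present.

The same pipeline runs on real data by pointing `--bundle` at a directory
with `proteomes/*.fasta`, `alignments/*.fasta`, `roles.tsv` and
`registry.tsv` (a 32-family NPC registry ships with the package:
`egt_screen.seqio.default_registry()`).

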