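# pfssnv

Analysis pipeline for how germline and somatic single-nucleotide variants
(in protein coordinates) distribute over protein functional sites — PTM,
enzyme active and ligand binding residues — and their ±20-residue
neighborhoods. The package covers:

- **io_model** — domain types, FASTA/TSV readers with auditable rejection
  reports, variant collapsing and cancer-term (DO-slim) unification;
- **sequence_mapping** — deterministic global alignment (affine gaps) for
  lifting annotations between sequence revisions;
- **site_effects** — loss/retained/gain effect calls from per-PTM residue
  tolerance rules and the N-X(≠P)-[S/T] N-glycosylation sequon, plus the
  variant × site neighborhood join;
- **occurrence_stats** — global per-residue SNV rates, percent of sites
  impacted per class, ±20 fold-change profiles and the site-vs-neighbors
  one-sample t-test;
- **enrichment** — exact directional binomial tails with an amino-acid
  background (site enrichment) and a patient-level background (per-cancer
  recurrence), with Bonferroni control;
- **pancancer_prioritize** — observed/expected fold-change matrix per
  (cancer, site type), deterministic complete-linkage clustering with
  Newick export, two-criterion key-variant selection and SMG/CGC gene-list
  intersection;
- **synthetic_data** — a seedable generator of proteomes, site tables and
  SNV/patient tables with planted depletion/enrichment effects, used as
  the test surface for every stage.

## CLI

Generate a synthetic fixture bundle, then run the full pipeline:

```sh
pfssnv simulate --config config.yaml --out bundle/
pfssnv map \
  --proteome bundle/proteome.fasta \
  --snv bundle/snvs.tsv \
  --sites bundle/sites.tsv \
  --do-map bundle/do_slim_map.tsv \
  --smg bundle/genes_smg.txt --cgc bundle/genes_cgc.txt \
  --out results/
```

Outputs include annotation, profile, t-test, pan-cancer matrix/tree,
patient-enrichment and key-variant tables, all TSV. Use
`pfssnv unify --old old.fasta --new new.fasta --annotations sites.tsv
--out lifted.tsv` to lift site positions between sequence revisions
(dropped/flagged positions go to a sidecar report). `--uniprot-headers`
parses `sp|ACC|NAME` FASTA headers; `--log-level` adjusts verbosity.

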