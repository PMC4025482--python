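# zipperscan

Leucine-zipper motif analysis for short peptides, built around a concrete
genetics question: can a single Ser→Leu missense change in the N-terminus of
the *Drosophila* Hox protein SCR create a new oligomerization motif, and does
that explain why the mutant allele antagonizes the wild-type one
(antimorphy)?

The package provides, as a reusable and tested pipeline:

- **Heptad and zipper detection** (`heptad_zipper`): every 7-residue window
  (*a b c d e f g*) of a peptide is assessed for hydrophobic residues at the
  core positions *a* and *d* (optionally leucine at *d*), with proline
  excluded as a helix breaker; passing windows that abut at exactly
  7-residue spacing form putative zipper calls, with two consecutive
  in-register heptads as the minimal zipper.
- **Helical wheel and face summary** (`helix_tools`): projection at 100° per
  residue (ideal α-helix, 3.6 residues/turn) with per-face amphipathicity
  statistics — hydrophobic fraction of the a/d core, polarity of b/c/f, and
  charge at the specificity positions e/g.
- **Sequence-logo statistics** (`helix_tools`): per-position residue
  frequencies and information content in bits,
  `info(pos) = log2(20) − H(pos)`, with an optional small-sample correction.
- **Rule-based secondary-structure inference** (`ss_homology`): gapless
  matching of query substrings against a database of structure-annotated
  sequence windows. A match is accepted when it is ≥ 6 residues (or an
  identical 5-mer), has ≤ 2 substitutions, every substitution has a
  BLOSUM62 score ≥ 0, and both scores are strictly positive when there are
  two; identical matched peptides are kept once per protein family.
  Accepted matches vote per residue to give an H/E/C/T consensus.
- **Allelic-interaction statistics** (`allelic_interaction`): the additive
  null — a trans-heterozygote should show the **sum** of the two
  hemizygote activities — with SEMs combined in quadrature, a z score for
  departures (inhibitory / additive / synergistic), summary-statistic t
  tests `t = (m₁ − m₂)/√(sem₁² + sem₂²)`, and per-tissue hypomorphy reports.
- **Synthetic data with planted truth** (`synthetic_data`): seeded
  generators for peptides with planted heptads, structure databases with
  planted homologous windows plus shuffled decoys, per-fly phenotype counts
  with a planted interaction effect, and heptad alignments around a
  consensus.

The two 19-residue query sequences (wild type `FAMSSYQFVNSLACYPQMN` and the
Ser→Leu variant `FAMSLYQFVNSLACYPQMN`) and the published phenotype summary
tables are packaged as fixtures under `zipperscan.datasets`.

## Worked example

```python
import zipperscan as z

wt, mut = z.datasets.scr_queries()

for pep in (wt, mut):
    hits = z.enumerate_heptads(pep)
    top = z.call_zippers(hits)[0]
    print(pep.id, [(h.start, h.window) for h in hits if h.passes],
          "zipper:", top.is_zipper)

p13 = z.datasets.scr_phenotypes(2013)
a = z.datasets.phenotype(p13, "Scr+/pb34", "sex_comb")
b = z.datasets.phenotype(p13, "Scr14/pb34", "sex_comb")
obs = z.datasets.phenotype(p13, "Scr14/Scr+", "sex_comb")
res = z.classify_interaction(z.additive_expectation(a, b), obs)
print(f"expected {res.expected_mean:.1f}, observed {res.observed_mean:.1f}, "
      f"z = {res.z:.1f} -> {res.call}")
```

prints

```
Scr_plus [(9, 'VNSLACY')] zipper: False
Scr14 [(2, 'AMSLYQF'), (5, 'LYQFVNS'), (9, 'VNSLACY')] zipper: True
expected 8.7, observed 7.0, z = -9.8 -> inhibitory
```

The wild-type N-terminus carries a single passing heptad (`VNSLACY`) and no
zipper. The Ser→Leu variant gains a second in-register heptad (`AMSLYQF`,
7 residues upstream of `VNSLACY`), so the top call is a two-heptad zipper
spanning residues 2–15. (A third, off-register single heptad is also
reported; only in-register runs form zipper calls.) On the genetics side,
the two hemizygotes alone account for 6.2 + 2.5 = 8.7 sex-comb bristles, yet
the trans-heterozygote shows only 7.0 — roughly ten combined standard errors
below the additive expectation — so the interaction is called inhibitory:
the mutant allele suppresses wild-type activity.

The same analyses are available from a shell:

```sh
zipperscan scan --fasta queries.fasta --out hits.json
zipperscan wheel --fasta queries.fasta --register 2 --out wheel.json
zipperscan sspredict --fasta queries.fasta --db windows.tsv --out pred.json
zipperscan interact --table pheno.tsv --pair "Scr+/pb34,Scr14/pb34" \
    --observed "Scr14/Scr+" --tissue sex_comb --out result.json
zipperscan simulate peptide --seed 17 --out sim/
```

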