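# sh3spot

Analysis of SH3-domain binding specificity from SPOT peptide arrays.

SH3 domains are ~60-residue peptide-recognition modules that bind
proline-rich ligands.  A SPOT experiment probes one tagged domain against a
membrane of synthesized 15-mer peptides; the spot intensities form the
domain's *binding profile* over the library.  Given raw intensities for a
panel of domains (each with family and species labels), this package

1. **normalizes** the profiles — log2 transform, replicate averaging, and
   median scaling, so that per-membrane exposure differences cancel exactly;
2. **maps the specificity landscape** — the pairwise Pearson correlation
   matrix of profiles, hierarchically clustered (distance `1 − r`, average
   linkage) and cut into the canonical specificity classes
   Type I (`+xxPxxP`), Type II (`PxxPx+`) and Type III (polyproline),
   labeled by the majority motif class of each cluster's top-binding
   peptides;
3. **builds PWMs** — anchor-aligns a domain's top-binding peptides and turns
   the block into a 15-column position-weight matrix
   `f[pos][a] = (count + pseudocount) / (rows + 20·pseudocount)`, with
   information-content logo export
   `IC = log2 20 + Σ_a f log2 f`, letter height `f·IC`;
4. **scans proteomes** — every 15-residue window `w` is scored
   `S(w) = Σ_pos Σ_a f[pos][a]·PAM250[w[pos], a]`, calibrated against a
   null of 1000 random 15-mers drawn from the background composition;
   upper-tail p-values (Gaussian fit to the null) are converted to
   q-values by Benjamini–Hochberg across all windows of the scan, and
   windows with `q < 1e-4` are reported as hits with their motif class;
5. **relates sequence to specificity** — for every within-family domain
   pair, percent identity (global alignment, BLOSUM62, gap 10/0.5) versus
   profile correlation, with a permutation-tested Spearman association and
   a per-family outlier flag for high-identity / low-correlation pairs
   (the signature of a binding-specificity switch).

A fully seeded synthetic-data module generates libraries, intensities,
domain families and proteomes with known ground truth, so every stage is
testable end to end without membrane images.  See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

Run the whole chain on a synthetic study (24 domains = 6 families × 4
species, 292-peptide library, 2 replicates):

```sh
$ sh3spot all --seed 7 --out-dir run
simulate: wrote library (292 probes), 24 domains, 100 proteins -> run
normalize: 292 probes x 24 domains -> run/profiles.tsv
cluster: 24 domains, k=3, classes={'II': 8, 'I': 8, 'III': 8} -> run
pwm: fam02-Ag anchor_class=III n=10 -> run/fam02-Ag.pwm
scan: 5 significant windows in 5 runs (q<0.0001, gaussian) -> run/hits.tsv
conserve: 36 pairs, Spearman rho=0.967 (perm p=0.0001) -> run
all: pipeline artifacts in run
```

Reading the output: the k=3 cut of the profile-correlation dendrogram
assigns all 24 domains to the three specificity classes (8 each, matching
the simulated family classes).  The PWM built from the top-10 binders of a
Type III domain recovers planted polyproline sites in the proteome at
`q < 1e-4`:

```
protein_id  start  end  window           score    p          q          motif_class
prot0014    4      18   FGKRTFTPPPPPPPP  23.2924  9.235e-09  6.048e-05  I*
prot0016    128    142  QNQLIINPPPPPPPQ  22.3735  1.997e-08  9.183e-05  III
...
```

(all five hit runs overlap planted sites; `start`/`end` are 1-based
inclusive in the TSV report, 0-based half-open in the BED file).  The
conservation stage reports a strong rank association between within-family
sequence identity and profile correlation (ρ = 0.967, permutation
p = 1e-4), since the simulation diverges sequences and profiles at coupled
per-family rates.

Every stage is also available separately (`sh3spot simulate | normalize |
cluster | pwm | scan | conserve`) and as library functions; `--config
file.yaml` supplies defaults, explicit flags win, and all outputs are
byte-reproducible under a fixed `--seed`.

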