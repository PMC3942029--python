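# mulescan

Tools for discovering prokaryotic **Mutator-like (MULE) transposase
families** and characterizing the transposable elements (TEs) they
mobilize — insertion sequences, transposons and integrative conjugative
elements (ICEs).

DDE transposases of the Mutator superfamily are poorly conserved at the
sequence level, so single similarity searches miss most of them.  `mulescan`
implements the comparative-genomics workflow that recovers them anyway, as a
tested, reusable pipeline exercised end-to-end on synthetic genomes with
planted elements and known ground truth:

1. **Cascade profile search** (`mulescan.cascade`) — iterative homolog
   expansion: a matrix search from a seed transposase, hits filtered at
   E ≤ 0.005 and query coverage ≥ 60%, a position-specific profile search,
   and re-querying from the most tree-distant retained hit (average-distance
   tree on BLOSUM62 distances), up to 7 rounds.
2. **Family delineation** (`mulescan.network`) — all-against-all
   Smith–Waterman similarities, edges kept at E < 10⁻⁴ with weight
   −log₁₀ E, clustered by a from-scratch **Markov Cluster algorithm**
   (inflation 1.2).
3. **Element boundary calling** (`mulescan.boundaries`) — transposase CDS
   ± 400 bp mapped back to the genome; with more than three copies the modal
   HSP start/end give the boundaries, extended when hits reach the window
   edge; boundaries are validated jointly by **terminal inverted repeats**
   (IRs, 18–39 bp, conserved terminal C, ≥83% complementarity) and
   **direct repeats** (DRs / target-site duplications of 8–9 bp), plus
   detection of the two-ORF −1 programmed frameshift organization.
4. **Insertion-site specificity** (`mulescan.sitespec`) — 300 bp junction
   flanks, a paired −35/−10 position-weight-matrix scan for σ^A promoters
   (spacer 15–19 bp), and the positional enrichment profile
   r(d) = promoters at distance d / all promoters within 30 bp of the
   junction (IRl side negative, IRr side positive), orientation bias and DR
   consensus motifs.
5. **Conservation and motif discovery** (`mulescan.conservation`) —
   plotcon-style windowed BLOSUM62 conservation curves (windows 15/10 aa),
   DDE-triad anchoring, the C/D(2)H signature scan 11–19 aa downstream of
   D2, N1/N2 domain localization, and differential conservation between
   group pairs (the promoter-targeting signature).
6. **Synthetic data with truth** (`mulescan.simulate`, `mulescan.fixtures`)
   — protein families diverged from ancestral transposases, genomes with
   multi-copy planted elements, and three insertion-site models:
   promoter-offset (−35 box 15–17 bp from the IRr junction, mode 16),
   AT-rich 8-mer target (`AANATNTT`), and uniform.

## Worked example

Generate the five-family synthetic protein set and recover the families
from the similarity network:

```sh
$ mulescan fixtures families5 --seed 1 --outdir fx
fx/families5.proteins.fasta
fx/families5.truth.tsv
$ mulescan cluster fx/families5.proteins.fasta --out-prefix fx/families5
5 clusters over 40 proteins
```

The 40 proteins (8 per family, within-family identity ≈ 65%, between-family
≈ 16%) cluster into exactly the five planted families.

Insertion-site specificity, from the library:

```python
from mulescan import fixtures, sitespec

genome, truth, _ = fixtures.make_promoter_bias(7, n_insertions=500)
flanks = sitespec.extract_junction_flanks(truth.itertuples(), str(genome.seq))
profile = sitespec.profile_from_flanks(flanks)
print(f"junctions={profile.n_junctions} promoters={profile.n_promoters_total} "
      f"peak={profile.peak_position:+d} bp ratio={profile.peak_ratio:.2f}")
```

prints

```
junctions=1000 promoters=520 peak=+16 bp ratio=0.46
```

i.e. of the 520 σ^A promoters detected within 30 bp of the 1,000 element
junctions, 46% sit exactly 16 bp from the IR-right junction — the oriented,
fixed-distance insertion upstream of promoters that characterizes this
element family; the IR-left side stays at the uniform background level.

Other fixture profiles: `promoter_bias`, `ish6_motif`, `uniform_te`,
`frameshift`, `chain_homology` (see `mulescan fixtures --help`), and
subcommands `cascade`, `bounds`, `sitespec`, `consmotif`, `run`.

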