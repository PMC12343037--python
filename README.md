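# siteseek

Active-site structural motif search: find proteins in a collection of
structure files whose local 3D arrangement of a few chosen residues matches
a seed protein's active site, independent of overall sequence or fold
similarity.

Sequence search (BLAST) and global structure search (FoldSeek-style) both
rank proteins by *overall* similarity. But function often lives in a handful
of residues — a Ser/Asp/His catalytic triad, a kinase gatekeeper pocket —
whose geometry can be conserved across otherwise unrecognizably diverged
proteins. `siteseek` searches for exactly that local arrangement, which makes
it useful for enzyme mining (finding new candidate enzymes for a reaction)
and for flagging potential drug off-targets that share a binding-site
geometry.

## Algorithm

Given a seed structure with three anchor residues (positions
$a_1, a_2, a_3$), optional additional residues, and per-position sets of
accepted amino-acid types, each query structure is processed as:

1. **Enumerate** all assignments of type-compatible query residues to the
   three anchors.
2. **Pre-screen**: keep a candidate triad only if each pairwise Cα distance
   satisfies $|d^{query}_{ij} - d^{seed}_{ij}| < 3\,\text{Å}$; if more than
   2000 candidates survive, a reproducible random subset of 2000 is kept.
3. **Superpose**: compute the least-squares optimal proper rotation $R$ and
   translation $t$ overlaying the query triad's Cα/Cβ atoms onto the seed's
   (Kabsch algorithm via SVD, reflections rejected).
4. **Score**: over the mapped residues (anchors, recovered additional
   residues, and ±4 sequence neighbors around each),

   $$\text{score} = \frac{\overline{d}}{n_{\text{mapped}}}, \qquad
     \overline{d} = \frac{1}{n_{\text{mapped}}}\sum_k d_k,$$

   where $d_k$ is the post-transform mean Cα/Cβ distance of mapped pair
   $k$. Missing additional residues shrink $n_{\text{mapped}}$ and inflate
   the score. A structure is accepted when its best mapping scores below
   1 Å (default).
5. **Report** two whole-structure metrics under the same transform: the
   *structural mapping percentage* (percent of query Cα atoms pairable with
   seed Cα atoms within 2 Å, via dynamic programming) and the *structural
   local similarity* (a run-length-weighted score in [0, 1] over consecutive
   aligned stretches of 5/10/15/20 residues).

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

Generate a small synthetic benchmark (60-residue helical pseudo-proteins
with a planted Ser/Asp/His triad; decoys break either the residue types or
the triad geometry) and search it with the planted site:

```bash
siteseek make-fixtures --n-positives 3 --n-decoys 4 --jitter 0.3 \
    --rng-seed 7 --out demo/fixtures
# 7 structures + seed.pdb (site at (11, 31, 51)) -> demo/fixtures

siteseek search --seed demo/fixtures/seed.pdb --anchors 11,31,51 \
    --queries demo/fixtures --out demo/results.tsv
# 4 hit(s) of 8 structures -> demo/results.tsv
```

`demo/results.tsv`:

```
structure_id	mapping	score	n_mapped	structural_mapping_percentage	structural_local_similarity
seed	11:11;31:31;51:51	0.000000	27	100.0000	1.000000
positive_002	11:11;31:31;51:51	0.000797	27	100.0000	1.000000
positive_000	11:11;31:31;51:51	0.001283	27	100.0000	1.000000
positive_001	11:11;31:31;51:51	0.003449	27	100.0000	1.000000
```

The seed matches itself with score exactly 0 and 100% of its residues
mapped. The three planted positives are recovered with scores well below the
1 Å threshold (`n_mapped` = 27: 3 anchors + 24 sequence neighbors at the
default ±4 window). All four decoys are rejected — wrong-type decoys have no
compatible triad to enumerate, wrong-geometry decoys fail the 3 Å distance
pre-screen — so they do not appear in the table.

Searching real structures works the same way: point `--seed` at a PDB/mmCIF
file, give the anchor positions (e.g. a catalytic triad), optionally
`--additional 393,478` and `--subs 790:THR,MET,ILE` to accept substitutions
at a position, and `--queries` at a directory of models.

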