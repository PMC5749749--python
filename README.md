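# localsw

Smith-Waterman local sequence alignment for DNA, RNA and protein, with
basic and affine gap penalties, recovery of multiple sub-optimal hits,
a seven-parameter hit-filtering scheme, and output as a tab-separated
table or SAM with per-hit quality tags. Built for sequence-analysis
workflows that need *inspectable* alignments — coordinates, aligned
strings, coverage and identity for every reported hit — rather than just
the best score.

## The algorithm

For a query `q` (length n) and target `t` (length m) with substitution
scores `s(a,b)` and non-negative penalties `g_o` (gap open) and `g_e`
(gap extension), the engine fills local-alignment matrices with scores
floored at zero.

Basic gap model (`g_e = 0`; every gap column costs `g_o`):

    H(i,j) = max(0, H(i-1,j-1) + s(q_i,t_j), H(i-1,j) - g_o, H(i,j-1) - g_o)

Affine gap model (Gotoh; a gap of length L costs `g_o + (L-1) g_e`):

    M(i,j) = max(0, s(q_i,t_j) + max(M, I, J)(i-1,j-1))
    I(i,j) = max(M(i-1,j) - g_o, I(i-1,j) - g_e)      # gaps in the target
    J(i,j) = max(M(i,j-1) - g_o, J(i,j-1) - g_e)      # gaps in the query

The affine model therefore holds three score grids instead of one
(30,000 interior cells instead of 10,000 for a 100x100 pair). A per-cell
direction record (winning matrix + move) drives the traceback; every
cell at or above `max(minimum_score, lower_limit_score * best)` starts a
traceback, highest score first, and starts consumed by an earlier trace
are skipped.

Each hit gets five derived metrics — query coverage, query identity,
relative score (score / shorter sequence length), base score
(score / alignment length) and the theoretical maximum score
(shorter length x maximum match score) — and must pass all seven filter
thresholds (defaults: `lower_limit_score` 1.0, `minimum_score` 30,
`filter_factor` 0.2, `query_coverage` 0.2, `query_identity` 0.2,
`relative_score` 2.0, `base_score` 2.0) to be reported.

Matrix filling runs either sequentially or on a deterministic
block-wavefront backend: the grid is cut into blocks processed in
anti-diagonal batches, blocks within a batch run on worker threads, and
the result is cell-for-cell identical to the sequential fill for any
worker count or block size.

## Worked example

```sh
python - <<'EOF'
from localsw import HomologySpec, generate_batch
generate_batch(2, HomologySpec(length=60, identity=0.9, indel_rate=0.02,
                               seed=4), "demo")
EOF
localsw demo/queries.fasta demo/targets.fasta --loglevel WARNING
```

prints one tab-separated row per passing hit (aligned strings truncated
here for width):

```
query_id  target_id  score    query_start  query_end  target_start  target_end  matches  mismatches  gap_columns  query_coverage  query_identity  relative_score  base_score  ...
q0001     t0001      169.000  1            55         17            71          45       9           2            0.917           0.750           2.817           3.018       ...
q0002     t0002      235.000  1            59         22            79          53       5           1            0.983           0.883           3.917           3.983       ...
```

Reading the first row: residues 1-55 of query `q0001` align to residues
17-71 of target `t0001` with 45 matches, 9 mismatches and 2 gap columns,
raw score 169; the alignment covers 91.7% of the query, matches 75% of
its residues, and scores 2.817 per residue of the shorter sequence —
all above the default thresholds. The four decoy targets in the batch
produce no rows: no local alignment against them survives the filters.

Add `-g 1` for affine gaps, `--matrix FILE` for a custom substitution
table (NCBI/EMBOSS dialect), `--outputformat SAM -o hits.sam` for SAM
output with `AS`/`QC`/`QI`/`RS`/`BS` tags, `--device parallel-CPU
--number_of_jobs 4` for the threaded backend, and `-c run.ini` to load
a saved configuration. `localsw -h` lists everything.

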