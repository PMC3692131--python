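# colonyscreen

Analysis of array-based colony fitness screens: quantify colony sizes
from photographs of pinned agar plates, correct the systematic biases
that plague plate-based measurements, filter untrustworthy colonies,
and compute multiplicative genetic-interaction scores against a
matched control screen.

## Who this is for

Labs running small- to medium-scale screens of ordered mutant arrays
(SGA-style double-mutant screens, chemical-genomic screens, or any
assay where colony size on solid agar is the fitness proxy).  The
supported pinning densities are 96 (8 × 12), 384 (16 × 24), 768 (two
interleaved 384 arrays on a 32 × 48 grid) and 1536 (32 × 48) colonies
per plate.

## The model

Colony size is a noisy, biased readout of strain fitness.  Three
multiplicative biases are corrected, in order:

1. **plate effect** — every plate is rescaled so its median colony
   size matches a common target (valid because interaction effects are
   rare, so most colonies have wild-type fitness);
2. **row/column effect** — outer rows and columns grow larger from
   extra nutrient access; each row and column is divided by its median
   relative to the plate median;
3. **spatial effect** — uneven agar thickness produces smooth regional
   trends, divided out via a running 2-D median surface (default 7 × 7
   window).

After normalization, sizes are converted to fitness by dividing by the
control-plate median *C*, and each double mutant is scored with the
multiplicative model

    score = W_ij − W_i · W_j

where *W_ij* is the observed double-mutant fitness, *W_i* the query
fitness (plate-wide median of the experiment) and *W_j* the array-
strain fitness (median of its technical replicates on the control).
Negative scores are aggravating interactions (score ≈ −1 is synthetic
lethality), positive scores alleviating/suppressing.  As rules of
thumb from screens of this design: scores below −0.3 are strong and
visible by eye, |score| < 0.1 rarely reproduces, and positive scores
in 0.1–0.3 deserve caution because of nutrient competition from small
neighbours.

Four filters annotate colonies whose sizes cannot be trusted:
replicate outliers (jackknife, `JK`), array genes chromosomally linked
to the query (`LK`, default 200 kb), implausibly large colonies (`BG`,
> 1.5 × plate median) and competition-suspect positives (`CF`).

## Worked example

Simulate one 96-format screen with known ground truth, normalize the
control/experiment pair onto a common scale, and score it:

```python
import io
from colonyscreen import (FORMATS, SyntheticScreenConfig, simulate_screen,
                          normalize_plates, score_screen, write_score_records)

cfg = SyntheticScreenConfig(format=FORMATS[96], seed=7)
truth, ctrl, exp = simulate_screen(cfg)
nc, ne = normalize_plates([ctrl, exp])
records = score_screen(ne, nc, query="YML032C")
buf = io.StringIO()
write_score_records(records[:6], buf)
print(buf.getvalue())
```

```
1	1	963	sim_dm_query_1_r1.dat	YML032C	1	627.091	0.242	status=CF
1	2	521	sim_dm_query_1_r1.dat	YML032C	2	370.446	-0.415	NA
1	3	714	sim_dm_query_1_r1.dat	YML032C	3	568.259	0.050	NA
1	4	557	sim_dm_query_1_r1.dat	YML032C	4	434.254	-0.227	NA
1	5	713	sim_dm_query_1_r1.dat	YML032C	5	562.154	-0.225	NA
1	6	637	sim_dm_query_1_r1.dat	YML032C	6	539.372	0.163	status=CF
```

The nine tab-separated columns are: row, column, raw colony size,
plate id, query gene, array gene, normalized size, interaction score
and key=value annotations (`NA` when empty).  Here position (1, 2)
carries an injected ε = −0.4 interaction and is recovered with a score
of −0.415; the two positives adjacent to strong negatives are flagged
`status=CF` (competition suspects).  The generator injected four
strong interactions on this plate; their recovered scores are −0.415,
−1.058, −0.688 and −1.148 against true effects of −0.4, −1, −0.4, −1.

The same pipeline runs from the shell:

```sh
colonyscreen simulate --format 96 --seed 5 --render --out demo/
colonyscreen run --format 96 --out demo/results demo/*.dat
colonyscreen viz --scores demo/results/sim0_dm_query_1_r1.dat.scores.tsv \
    --format 96 --histogram demo/hist.png --select -10 -0.3
```

`run` also accepts plate photographs (PNG/JPEG/TIFF) named by the
five-field convention `prefix_type_query_plate_suffix.ext`, e.g.
`2013-05-12_ctrl_YML032C_2_rep3.jpg` is the control for crossing the
YML032C query into the second array plate.

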