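# opikin

Objective performance indicators (OPIs) from robotic-console kinematics, with
a per-step comparison of surgeon cohorts — built around the eight-step
ontology of robotic Roux-en-Y gastric bypass (r-RYGB).

Surgical consoles record the 3-D motion of each hand's instrument tip and
hand controller, together with the spans during which the surgeon is actively
driving ("active console time").  From these streams `opikin` computes, per
surgical step and operator:

| metric | definition |
| --- | --- |
| total task duration (s) | annotated step time attributed to the operator |
| active console time (s, %) | driving time and its share of the task duration |
| per-hand active time (s, %) | same, per hand controller |
| instrument path length (cm) | total tip travel during that hand's active time |
| path-length speed (cm/s) | path length / active time |
| bimanual dexterity | dominant : non-dominant path-length ratio |
| workspace volume (cm³) | convex hull of pooled both-hand tip positions |
| workspace volume rate (cm³/s) | hull volume / active console time |
| workspace per path length (cm²) | hull volume / total path length |
| console sensitivity | tip / wrist path-length ratio (motion-scaling check) |

Cohorts (e.g. attending vs trainee) are compared per step × metric with a
normality-gated procedure: Shapiro–Wilk in each group at α = 0.05; Student's
independent *t* test with mean (95 % CI) summaries when both groups pass,
otherwise a two-sided Mann–Whitney *U* test with median [IQR] summaries.
*p* < 0.05 is flagged; no multiple-testing correction by default (a
Benjamini–Hochberg option exists).

Because clinical console recordings are proprietary, the package ships a
fully seeded synthetic case generator whose per-step speed, duty cycle,
hand-dominance, workspace spread, and motion scale are programmed — giving
ground truth for every metric and a calibration bench for the statistics.

## Worked example

Simulate a 10 + 10-case two-cohort study with the built-in effect preset,
compute OPIs for every bundle, and compare the cohorts:

```sh
opikin simulate --seed 7 --cases 10 --out data/
# -> wrote 20 bundles to data/

python - <<'EOF'
from pathlib import Path
from opikin.io import read_case_bundle, write_opi_table
from opikin.ontology import build_step_windows
from opikin.opi import compute_step_opis
rows = []
for b in sorted(p for p in Path("data").iterdir() if p.is_dir()):
    case = read_case_bundle(b)
    rows.extend(compute_step_opis(case, build_step_windows(case)))
write_opi_table(rows, "opis.csv")
EOF

opikin compare opis.csv --group-a attending --group-b resident,fellow -o table.csv
# -> wrote 72 comparison rows to table.csv
```

The significant rows of `table.csv` for that seed:

```
                     step                       metric  median_a  median_b    test_used p_value
               dissection               speed_dom_cm_s     6.019     2.804       t_test  <0.001
               dissection           bimanual_dexterity     1.608     0.782       t_test  <0.001
creation_of_gastric_pouch           pct_active_console    69.321    35.588       t_test  <0.001
creation_of_gastric_pouch            speed_nondom_cm_s     3.884     4.293       t_test   0.031
    hand_sewn_anastomosis           pct_active_console    37.824    18.399       t_test   0.043
    hand_sewn_anastomosis         workspace_rate_cm3_s     4.479    18.626       t_test  <0.001
    hand_sewn_anastomosis workspace_per_pathlength_cm2     0.535     2.174       t_test  <0.001
```

Group A is the attending cohort.  The generator programmed higher attending
dexterity and non-dominant speed in dissection, lower attending non-dominant
speed and higher active time in pouch creation, and higher active time with a
more confined (lower-rate) workspace in the hand-sewn anastomosis — the table
recovers those directions (at 10 cases per arm one programmed speed effect is
missed and two of the five null steps show α-level flags; at 20 + 20 cases
all six programmed effects are recovered in ≈ 98 % of replicates).  Note the
two workspace normalizations agree on the hand-sewn-anastomosis finding.

Other subcommands: `opikin validate <bundle>`, `opikin compute <bundle> -o
opis.csv`, `opikin calibrate --mode null|power`, `opikin config --show`.

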