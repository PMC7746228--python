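"""Screen a synthetic cohort of GRL-like proteins and decoys.

Generates 10 planted positives (seven TMs, intracellular N-terminus,
IL > EL, 350-500 aa) and 10 decoys that each violate at least two of the
five retention criteria, then applies the screen.  With the default
"most or all" threshold (>= 4 of 5 criteria) exactly the positives
survive.
"""

from grlscreen.screen import screen_collection, screen_summary
from grlscreen.synthetic_data import make_cohort

records, topologies, truths = make_cohort(10, 10, seed=42)
results = screen_collection(records, topologies)

for res in results:
    flags = "".join(
        "+" if ok else "-"
        for ok in (res.c1_reciprocal, res.c2_length, res.c3_seven_tm,
                   res.c4_n_in, res.c5_il_gt_el)
    )
    verdict = "retained" if res.retained else "rejected"
    print(f"{res.protein_id:12s} criteria {flags}  {res.n_passed}/5  {verdict}")

summary = screen_summary(records, results)
print(f"\nretained {summary['n_retained']} of {summary['n_screened']}"
      " (the 10 planted positives; each decoy fails >= 2 criteria)")
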