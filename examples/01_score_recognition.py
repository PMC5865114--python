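"""Score one subject's recognition responses.

Builds a toy response set (4 picture pairs + 2 novel lures), then computes
hit/false-alarm percentages, the Confidence Score, and the pair trichotomy
(detailed / transformed / forgotten).
"""

import pandas as pd

from gistmem.behavior import SubjectBehavior, categorize_pairs, summarize_subject

trials = pd.DataFrame(
    [
        # picture_id, pair_id, type, emotion, response, confidence
        ("old_a", "a", "old", "neutral", "yes", 3),   # detailed: old yes ...
        ("rel_a", "a", "related", "neutral", "no", None),  # ... lure rejected
        ("old_b", "b", "old", "negative", "yes", 1),  # transformed: lure
        ("rel_b", "b", "related", "negative", "yes", 2),   # endorsed too
        ("old_c", "c", "old", "neutral", "no", None),  # forgotten: both "no"
        ("rel_c", "c", "related", "neutral", "no", None),
        ("old_d", "d", "old", "negative", "yes", 2),  # detailed
        ("rel_d", "d", "related", "negative", "no", None),
        ("nov_1", None, "novel", "neutral", "no", None),
        ("nov_2", None, "novel", "negative", "yes", 0),  # novel false alarm
    ],
    columns=["picture_id", "pair_id", "picture_type", "emotion", "response", "confidence"],
)

subject = SubjectBehavior(subject_id="demo", group="1d", trials=trials)
summary = summarize_subject(subject)

print(f"hit rate           : {summary.hit_pct:.2f} %")
print(f"FA related lures   : {summary.fa_related_pct:.2f} %")
print(f"FA novel lures     : {summary.fa_novel_pct:.2f} %")
print(f"Confidence Score   : {summary.confidence_score} (max 3 x n_old = 12 here)")
print(categorize_pairs(subject).to_string(index=False))
print("\nEach pair is classified from the two responses: a 'yes' to the lure")
print("means the gist survived but details did not (transformed).")
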