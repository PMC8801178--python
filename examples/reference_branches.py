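"""Identify reference branches on the packaged grass-style fixture tree.

A reference branch subtends the most recent common ancestor of a
maximal clade whose sampled tips all share one photosynthesis type;
sister clades known to be independent origins are kept apart with
forced splits supplied as configuration.
"""

import chloroconv as cc
from chloroconv.fixtures import study_forced_splits, study_tree
from chloroconv.reference_branches import branch_report_frame

tree = study_tree()
branches = cc.find_reference_branches(tree, forced_splits=study_forced_splits())

print(branch_report_frame(branches)[["branch_id", "type", "n_tips", "forced",
                                     "branch_length"]].to_string(index=False))
n_c4 = sum(b.type == "C4" for b in branches)
n_c3 = sum(b.type == "C3" for b in branches)
pairs = cc.enumerate_pairs(branches)
cats = [p.category for p in pairs]
print(f"\n{n_c4} C4 and {n_c3} C3 reference branches")
print(f"pairs: {cats.count('C4:C4')} C4:C4, {cats.count('C3:C4')} C3:C4, "
      f"{cats.count('C3:C3')} C3:C3")
# 13 C4 and 9 C3 branches give 78 + 117 + 36 = 231 unordered pairs: the
# unit at which convergent and non-convergent replacements are compared.
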