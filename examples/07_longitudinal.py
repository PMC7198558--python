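"""Serial-tumour analysis: force-calling, sharing, Jaccard, phylogeny.

Takes multi-sample cases from a synthetic cohort, force-calls each case's
aggregate variant set in every tumour, classifies variants as truncal or
private, computes inter-tumour Jaccard concordance, and builds a
minimum-event copy-number phylogeny rooted at a diploid outgroup.
"""

import numpy as np
import pandas as pd

from tgctk.cohort import CohortConfig, generate_cohort
from tgctk.longitudinal import (
    build_tree,
    classify_sharing,
    event_distance_matrix,
    force_call,
    jaccard_index,
    to_allele_arrays,
)

cfg = CohortConfig(n_cases=40, seed=23, samples_per_case={2: 0.5, 3: 0.5},
                   truncal_fraction=0.6)
samples, variants, profiles, truth = generate_cohort(cfg)
stages = {s.sample_id: s.stage for s in samples}

by_case: dict[str, list] = {}
for s in samples:
    by_case.setdefault(s.case_id, []).append(s.sample_id)
by_key: dict[tuple, dict] = {}
for v in variants:
    by_key.setdefault((v.case_id, v.variant_id), {})[v.sample_id] = v

case_id, sids = next((c, ss) for c, ss in by_case.items() if len(ss) == 3)
print(f"case {case_id}: tumours {sids}")

# force-call the case's aggregate variant set in every tumour
statuses = {}
for (cid, vid), per_sample in by_key.items():
    if cid != case_id:
        continue
    row = {}
    for sid in sids:
        v = per_sample.get(sid)
        alt, depth = (v.alt_reads, v.depth) if v else (0, 60)
        row[sid] = force_call(vid, sid, alt, depth).status
    statuses[vid] = row
presence = pd.DataFrame.from_dict(statuses, orient="index")[sids]
classes = classify_sharing(presence, stages)
print("sharing classes:", classes.value_counts().to_dict())

sets = {
    sid: {vid for vid, row in statuses.items() if row[sid] == "present"}
    for sid in sids
}
print(f"Jaccard primary vs metastasis: "
      f"{jaccard_index(sets[sids[0]], sets[sids[1]]):.0f}")

arrays = {sid: to_allele_arrays(profiles[sid]) for sid in sids}
D = event_distance_matrix(arrays)
print("\nminimum-event distances:")
print(D.round(0).to_string())
print("\nNewick:", build_tree(D))
# the two metastases derive from a shared precursor in the simulation, so
# they sit closer to each other than either does to the primary.
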