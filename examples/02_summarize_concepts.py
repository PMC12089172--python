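"""Computer-assisted summarization: suggest groups, apply a summary map.

Participants write free text; spelling variants and synonyms of the same
idea are grouped under researcher-named superordinate categories before any
quantitative analysis.
"""

from camkit.data import DEFAULT_SYNONYMS
from camkit.summarize import (
    SummaryMap,
    apply_summary,
    load_synonym_dictionary,
    osa_distance,
    search_terms,
    suggest_by_distance,
    synonym_groups,
    unsummarized_overview,
)
from camkit.synth import GenConfig, generate_cam_set, inject_text_noise

print(f"OSA distance dreams->dreasm: {osa_distance('dreams', 'dreasm')} "
      "(one adjacent transposition: a likely typo)")

cfg = GenConfig(n_cams=15, p_typo=0.2, seed=3)
cams, _ = generate_cam_set(cfg)
noisy, record = inject_text_noise(cams, cfg)
texts = [c.text for _, c in noisy.all_concepts()]

groups = suggest_by_distance(texts, max_dist=1)
print(f"\n{len(record['typo_pairs'])} typos planted; distance suggestions found "
      f"{len(groups)} groups, e.g.:")
for g in groups[:3]:
    print("  ", g.members)

digits = search_terms(texts + ["co2 tax"], "[[:digit:]]")
print(f"\nConcepts containing digits (regex [[:digit:]]): {digits}")

syn = synonym_groups(["war", "conflict", "health"],
                     load_synonym_dictionary(DEFAULT_SYNONYMS))
print(f"Synonym suggestion: {syn[0].members if syn else 'none'}")

smap = SummaryMap({m: g.representative for g in groups for m in g.members},
                  split_by_valence=False)
summarized = apply_summary(noisy, smap)
left = unsummarized_overview(summarized, smap)
print(f"\nAfter applying the map, {len(left)} unique texts remain unsummarized "
      "(the researcher's worklist).")
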