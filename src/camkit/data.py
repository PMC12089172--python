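"""Small built-in text fixtures for the synthetic generator and examples.

The vocabulary is a set of single-word terms of the kind participants draw in
attitude studies (climate, mobility, everyday life).  Terms were chosen to be
mutually distant under optimal string alignment (pairwise distance >= 3), so
that a single planted typo never turns one base term into a near-neighbor of
another -- which is what makes typo-recovery scoring well posed.

The synonym dictionary is a deliberately tiny stand-in for a real thesaurus;
real dictionaries plug in through the same mapping interface.
"""

DEFAULT_VOCABULARY: tuple[str, ...] = (
    "acceptance",
    "accountability",
    "anxiety",
    "biodiversity",
    "bureaucracy",
    "childhood",
    "climate",
    "community",
    "compromise",
    "conflict",
    "convenience",
    "creativity",
    "democracy",
    "education",
    "efficiency",
    "employment",
    "flexibility",
    "freedom",
    "friendship",
    "frustration",
    "government",
    "happiness",
    "health",
    "independence",
    "infrastructure",
    "innovation",
    "insecurity",
    "loneliness",
    "motivation",
    "nature",
    "opportunity",
    "pollution",
    "prosperity",
    "responsibility",
    "safety",
    "solidarity",
    "sustainability",
    "technology",
    "tradition",
    "uncertainty",
)

DEFAULT_SYNONYMS: dict[str, list[str]] = {
    "war": ["conflict", "combat"],
    "conflict": ["war", "dispute"],
    "happiness": ["joy", "contentment"],
    "joy": ["happiness"],
    "freedom": ["liberty", "independence"],
    "liberty": ["freedom"],
    "health": ["wellbeing"],
    "wellbeing": ["health"],
    "safety": ["security"],
    "security": ["safety", "insecurity"],
    "nature": ["environment"],
    "environment": ["nature"],
    "education": ["schooling"],
    "schooling": ["education"],
}
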