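"""Fixed English stopword list.

The list is frozen inside the package (rather than taken from an external
resource) so that preprocessing is a stable, versioned convention: golden
test values and any serialized document-term matrix are tied to exactly
this list.  It covers determiners, pronouns, auxiliaries, conjunctions,
common prepositions and a few high-frequency adverbs; domain words are
never stopworded.
"""

ENGLISH_STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are aren as at
    be because been before being below between both but by
    can cannot could couldn
    did didn do does doesn doing don down during
    each even ever every
    few for from further
    had hadn has hasn have haven having he her here hers herself him
    himself his how
    i if in into is isn it its itself
    just
    me more most mustn my myself
    no nor not now
    of off on once only or other ought our ours ourselves out over own
    same shan she should shouldn so some such
    than that the their theirs them themselves then there these they
    this those through to too
    under until up upon
    very
    was wasn we were weren what when where which while who whom why will
    with won would wouldn
    you your yours yourself yourselves
    """.split()
)
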