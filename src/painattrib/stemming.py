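"""English (Porter2 / Snowball) stemming.

This module implements the Porter2 English stemming algorithm from its
published rule description.  Stemming here is a *frozen preprocessing
convention*: every text-facing component of the package (lexicon
compilation, document-term matrices, word-frequency deltas) runs through
the same stemmer, so internal consistency — the same surface form always
maps to the same stem — is what the downstream analyses rely on.

Only lowercase ASCII input is expected; callers normalise case first
(see :func:`painattrib.corpus.preprocess`).
"""

from __future__ import annotations

from functools import lru_cache

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDING = frozenset("cdeghkmnrt")

# Irregular forms handled before the rule cascade.
_EXCEPTIONS = {
    "skis": "ski",
    "skies": "sky",
    "dying": "die",
    "lying": "lie",
    "tying": "tie",
    "idly": "idl",
    "gently": "gentl",
    "ugly": "ugli",
    "early": "earli",
    "only": "onli",
    "singly": "singl",
    "sky": "sky",
    "news": "news",
    "howe": "howe",
    "atlas": "atlas",
    "cosmos": "cosmos",
    "bias": "bias",
    "andes": "andes",
}

# Words left alone after step 1a.
_EXCEPTIONS_1A = frozenset(
    {"inning", "outing", "canning", "herring", "earring", "proceed", "exceed", "succeed"}
)

_STEP2_SUFFIXES = (
    ("ization", "ize"),
    ("ational", "ate"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("iveness", "ive"),
    ("tional", "tion"),
    ("biliti", "ble"),
    ("lessli", "less"),
    ("entli", "ent"),
    ("ation", "ate"),
    ("alism", "al"),
    ("aliti", "al"),
    ("ousli", "ous"),
    ("iviti", "ive"),
    ("fulli", "ful"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("abli", "able"),
    ("izer", "ize"),
    ("ator", "ate"),
    ("alli", "al"),
    ("bli", "ble"),
)

_STEP3_SUFFIXES = (
    ("ational", "ate"),
    ("tional", "tion"),
    ("alize", "al"),
    ("icate", "ic"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ness", ""),
    ("ful", ""),
)

_STEP4_SUFFIXES = (
    "ement",
    "ance",
    "ence",
    "able",
    "ible",
    "ment",
    "ant",
    "ent",
    "ism",
    "ate",
    "iti",
    "ous",
    "ive",
    "ize",
    "ion",
    "al",
    "er",
    "ic",
)


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS


def _regions(word: str) -> tuple[int, int]:
    """Return (r1, r2) start indices.

    R1 is the region after the first non-vowel following a vowel; R2 is
    the same definition applied within R1.  Words beginning ``gener``,
    ``commun`` or ``arsen`` take R1 immediately after that prefix.
    """
    n = len(word)
    r1 = n
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            r1 = len(prefix)
            break
    else:
        for i in range(1, n):
            if not _is_vowel(word, i) and _is_vowel(word, i - 1):
                r1 = i + 1
                break
    r2 = n
    for i in range(r1 + 1, n):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            r2 = i + 1
            break
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    """True if the word ends in a short syllable.

    A short syllable is either (a) a vowel followed by a non-vowel other
    than w, x or Y, preceded by a non-vowel, or (b) a vowel at the start
    of the word followed by a non-vowel.
    """
    n = len(word)
    if n == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    if n >= 3:
        return (
            not _is_vowel(word, n - 3)
            and _is_vowel(word, n - 2)
            and not _is_vowel(word, n - 1)
            and word[n - 1] not in "wxY"
        )
    return False


def _contains_vowel(word: str, start: int, end: int) -> bool:
    return any(_is_vowel(word, i) for i in range(start, end))


def _step0(word: str) -> str:
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            return word[: -len(suf)]
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith(("ied", "ies")):
        return word[:-2] if len(word) > 4 else word[:-1]
    if word.endswith(("us", "ss")):
        return word
    if word.endswith("s") and _contains_vowel(word, 0, len(word) - 2):
        return word[:-1]
    return word


def _step1b(word: str, r1: int) -> str:
    if word.endswith(("eedly", "eed")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= r1:
            return word[: -len(suf)] + "ee"
        return word
    for suf in ("ingly", "edly", "ing", "ed"):
        if word.endswith(suf):
            stem = word[: -len(suf)]
            if not _contains_vowel(stem, 0, len(stem)):
                return word
            if stem.endswith(("at", "bl", "iz")):
                return stem + "e"
            if stem.endswith(_DOUBLES):
                return stem[:-1]
            r1_stem, _ = _regions(stem)
            if r1_stem >= len(stem) and _ends_short_syllable(stem):
                return stem + "e"
            return stem
    return word


def _step1c(word: str) -> str:
    if (
        len(word) > 2
        and word[-1] in "yY"
        and not _is_vowel(word, len(word) - 2)
    ):
        return word[:-1] + "i"
    return word


def _step2(word: str, r1: int) -> str:
    for suf, repl in _STEP2_SUFFIXES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                return word[: -len(suf)] + repl
            return word
    if word.endswith("ogi"):
        if len(word) - 3 >= r1 and word[-4:-3] == "l":
            return word[:-1]
        return word
    if word.endswith("li"):
        if len(word) - 2 >= r1 and word[-3:-2] in _LI_ENDING:
            return word[:-2]
        return word
    return word


def _step3(word: str, r1: int, r2: int) -> str:
    for suf, repl in _STEP3_SUFFIXES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                return word[: -len(suf)] + repl
            return word
    if word.endswith("ative"):
        if len(word) - 5 >= r2:
            return word[:-5]
        return word
    return word


def _step4(word: str, r2: int) -> str:
    for suf in _STEP4_SUFFIXES:
        if word.endswith(suf):
            if suf == "ion":
                if len(word) - 3 >= r2 and word[-4:-3] in "st":
                    return word[:-3]
                return word
            if len(word) - len(suf) >= r2:
                return word[: -len(suf)]
            return word
    return word


def _step5(word: str, r1: int, r2: int) -> str:
    if word.endswith("e"):
        if len(word) - 1 >= r2:
            return word[:-1]
        if len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1]):
            return word[:-1]
        return word
    if word.endswith("l") and len(word) - 1 >= r2 and word[-2:-1] == "l":
        return word[:-1]
    return word


@lru_cache(maxsize=65536)
def stem(word: str) -> str:
    """Stem one lowercase word with the Porter2 (English Snowball) rules."""
    if len(word) <= 2:
        return word
    if word.startswith("'"):
        word = word[1:]
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]

    # Mark y's that function as consonants: initial y, or y after a vowel.
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in "aeiouy":
            chars[i] = "Y"
    word = "".join(chars)

    word = _step0(word)
    word = _step1a(word)
    if word in _EXCEPTIONS_1A:
        return word
    r1, r2 = _regions(word)
    word = _step1b(word, r1)
    word = _step1c(word)
    # Regions are defined on the original word's letter positions; suffix
    # rewrites never lengthen the word past them, so recomputing after the
    # destructive steps keeps indices aligned with the Snowball definition.
    r1, r2 = _regions(word)
    word = _step2(word, r1)
    r1, r2 = _regions(word)
    word = _step3(word, r1, r2)
    r1, r2 = _regions(word)
    word = _step4(word, r2)
    r1, r2 = _regions(word)
    word = _step5(word, r1, r2)
    return word.replace("Y", "y")
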