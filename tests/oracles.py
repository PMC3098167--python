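"""Brute-force oracles shared by the matcher tests.

Deliberately independent of the package's regex-based implementation:
token-level scans over case-folded query text.
"""


def oracle_matches(pattern_text: str, query: str) -> bool:
    """Token-by-token scan; cores must not contain whitespace."""
    query = query.casefold()
    tokens = query.split()
    for part in pattern_text.split("|"):
        part = part.strip()
        prefix = part.startswith("*")
        core = part[1:] if prefix else part
        suffix = core.endswith("*")
        core = (core[:-1] if suffix else core).strip().casefold()
        if prefix and suffix:
            hit = core in query
        elif prefix:
            hit = any(tok.endswith(core) for tok in tokens)
        elif suffix:
            hit = any(tok.startswith(core) for tok in tokens)
        else:
            hit = core in tokens
        if hit:
            return True
    return False


def random_corpus(rng, n_entries: int):
    """Random Swedish-flavoured query corpus with case variation."""
    from datetime import datetime

    from querytrends import QueryLogEntry

    words = ["kräk", "kräkningar", "kräksjuka", "feber", "influensa",
             "diarre", "diarré", "herpes", "ont", "barn", "åksjuka"]
    entries = []
    base = datetime(2006, 1, 2)
    for _ in range(n_entries):
        text = " ".join(rng.choice(words) for _ in range(rng.randint(1, 3)))
        if rng.random() < 0.3:
            text = text.upper() if rng.random() < 0.5 else text.capitalize()
        entries.append(QueryLogEntry(base, text))
    return words, entries


def random_patterns(rng, words, n_patterns: int):
    shapes = ["{}", "*{}*", "*{}", "{}*"]
    return ["|".join(rng.choice(shapes).format(rng.choice(words))
                     for _ in range(rng.randint(1, 3)))
            for _ in range(n_patterns)]
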