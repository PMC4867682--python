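"""Quality flags attached to per-pot and per-extract results.

Flags mark physically suspect values that are *retained* in the output
(never silently dropped); summary aggregation may exclude flagged
records depending on configuration.
"""

CLAMPED_SEED_P = "CLAMPED_SEED_P"
NEGATIVE_PDF_FERTILIZER = "NEGATIVE_PDF_FERTILIZER"
IMPOSSIBLE_RATIO = "IMPOSSIBLE_RATIO"
NEGATIVE_PDFF_RESIN = "NEGATIVE_PDFF_RESIN"
NEGATIVE_PMIC = "NEGATIVE_PMIC"

#: flags that exclude a pot from summary statistics when
#: ``exclude_flagged`` is enabled; CLAMPED_SEED_P is benign.
EXCLUDING_FLAGS = frozenset({NEGATIVE_PDF_FERTILIZER, IMPOSSIBLE_RATIO})


def join_flags(flags):
    """Render a set of flags as the semicolon-joined CSV column."""
    return ";".join(sorted(flags))


def split_flags(text):
    """Parse the semicolon-joined CSV column back into a set."""
    if not text or (isinstance(text, float)):
        return set()
    return {f for f in str(text).split(";") if f}
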