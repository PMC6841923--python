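"""Name normalization for hand-curated species and compound tables.

Curated metabolic-activity tables are typed by humans: the same compound shows
up as ``D-Glucose``, ``d-glucose`` and ``D-glucose ``.  Normalization is
case-insensitive with whitespace collapsed; stereo prefixes (``D-``/``L-``) are
kept, only case-folded, so ``D-xylose`` and ``L-xylose`` stay distinct.
"""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Return the canonical lookup key for a species or compound name."""
    if not isinstance(name, str):
        raise TypeError(f"name must be a string, got {type(name).__name__}")
    return _WS.sub(" ", name.strip()).lower()
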