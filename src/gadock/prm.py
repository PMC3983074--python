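"""Plain-text parameter (.prm) files controlling cavity definition, scoring
and search protocol.

Format: one ``KEY value`` pair per line; ``#`` starts a comment; values are
parsed as int/float/bool where possible.  ``WEIGHT.<term>`` keys override
individual scoring-function term weights.
"""

from __future__ import annotations

from .params import ScoringConfig

__all__ = ["parse_prm", "scoring_config_from_prm"]


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v.upper() in ("TRUE", "FALSE"):
        return v.upper() == "TRUE"
    return v


def parse_prm(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for raw in fh:
            s = raw.split("#")[0].strip()
            if not s:
                continue
            parts = s.split(None, 1)
            if len(parts) == 1:
                out[parts[0].upper()] = True
            else:
                out[parts[0].upper()] = _coerce(parts[1].strip())
    return out


def scoring_config_from_prm(prm: dict) -> ScoringConfig:
    sf = str(prm.get("SCORING_FUNCTION", "SF3")).upper()
    cfg = ScoringConfig.sf5() if sf == "SF5" else ScoringConfig.sf3()
    for key, val in prm.items():
        if key.startswith("WEIGHT."):
            cfg.weights[key[len("WEIGHT."):].lower()] = float(val)
    return cfg.validate()
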