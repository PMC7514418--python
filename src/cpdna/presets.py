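"""Default running modes (levels 1-15).

Lower levels are lighter and suit shorter sequences; higher levels add models,
deeper contexts, more simultaneous repeat pointers and a deeper competitive-
prediction context, and suit long sequences.  The table is monotone: total
model count, maximum context order, repeat-pointer budget (rpn) and CPCM
order are all non-decreasing in the level.

Forgetting factors follow the empirical pattern for this mixture type:
shallow models get small gamma (quick forgetting, below 0.9), deep models get
gamma near 0.95, and the order-6 model — which tracks the short periodicities
of DNA — sits in [0.75, 0.85].  The CPCM order runs from 4-5 at the lowest
levels (best for short sequences) to 16 from level 12 up (best for long
ones).
"""

from __future__ import annotations

from .codec import CodecConfig
from .fcm import CMConfig, STCMConfig
from .repeats import RepeatConfig

# master context-model list; levels take prefixes-with-insertions of this
_CM = {
    "A": CMConfig(k=4, alpha_num=1, alpha_den=1, gamma=0.70, ir_mode="forward"),
    "B": CMConfig(k=8, alpha_num=1, alpha_den=1, gamma=0.89, ir_mode="both"),
    "C": CMConfig(k=11, alpha_num=1, alpha_den=2, gamma=0.92, ir_mode="both"),
    "D": CMConfig(k=6, alpha_num=1, alpha_den=1, gamma=0.80, ir_mode="forward"),
    "E": CMConfig(k=13, alpha_num=1, alpha_den=8, gamma=0.94, ir_mode="both",
                  stcm=STCMConfig(max_subs=4, t=8, l=32)),
    "F": CMConfig(k=2, alpha_num=1, alpha_den=1, gamma=0.60, ir_mode="forward"),
    "G": CMConfig(k=16, alpha_num=1, alpha_den=16, gamma=0.95, ir_mode="both"),
    "H": CMConfig(k=18, alpha_num=1, alpha_den=32, gamma=0.95, ir_mode="both",
                  stcm=STCMConfig(max_subs=6, t=8, l=32)),
    "I": CMConfig(k=20, alpha_num=1, alpha_den=64, gamma=0.95, ir_mode="both"),
}

_CM_SETS = {
    1: "AB",
    2: "ABC",
    3: "ADBC",
    4: "ADBCE",
    5: "FADBCE",
    6: "FADBCEG",
    7: "FADBCEG",
    8: "FADBCEGH",
    9: "FADBCEGH",
    10: "FADBCEGHI",
    11: "FADBCEGHI",
    12: "FADBCEGHI",
    13: "FADBCEGHI",
    14: "FADBCEGHI",
    15: "FADBCEGHI",
}


def _rm(k_r: int, rpn: int) -> RepeatConfig:
    # a_miss=3 starts a fresh pointer at q=1/4 (uniform): a spawned copy must
    # earn confidence with hits, so chance k-mer matches in random background
    # cost (almost) nothing when their class is selected.
    return RepeatConfig(k_r=k_r, rpn=rpn, a_hit=1, a_miss=3,
                        deactivate_below=0.4, gamma_r=0.1, ir_enabled=True,
                        max_positions_per_kmer=16)


_RM_SETS = {
    1: (_rm(8, 8),),
    2: (_rm(8, 8),),
    3: (_rm(8, 12),),
    4: (_rm(8, 16), _rm(13, 8)),
    5: (_rm(8, 16), _rm(13, 8)),
    6: (_rm(8, 20), _rm(13, 12)),
    7: (_rm(8, 20), _rm(13, 12)),
    8: (_rm(8, 24), _rm(13, 16)),
    9: (_rm(8, 24), _rm(13, 16)),
    10: (_rm(8, 32), _rm(13, 24)),
    11: (_rm(8, 32), _rm(13, 24)),
    12: (_rm(8, 32), _rm(13, 24)),
    13: (_rm(8, 40), _rm(13, 32)),
    14: (_rm(8, 40), _rm(13, 32)),
    15: (_rm(8, 40), _rm(13, 32)),
}

_CPCM_ORDER = {1: 4, 2: 5, 3: 6, 4: 8, 5: 9, 6: 10, 7: 11, 8: 12, 9: 13,
               10: 14, 11: 15, 12: 16, 13: 16, 14: 16, 15: 16}

LEVELS = tuple(range(1, 16))


def level_preset(level: int, seed: int = 0) -> CodecConfig:
    """The documented default configuration for ``level`` in 1..15."""
    if level not in _CPCM_ORDER:
        raise ValueError(f"level must be in 1..15, got {level}")
    cms = tuple(_CM[c] for c in _CM_SETS[level])
    return CodecConfig(
        cms=cms,
        rms=_RM_SETS[level],
        k_c=_CPCM_ORDER[level],
        alpha_c_num=1,
        alpha_c_den=1,
        seed=seed,
    )
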