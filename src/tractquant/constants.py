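"""Shared vocabulary: tract families, variables, node/segment layout.

Six white-matter tract families are analyzed: the inferior fronto-occipital
fasciculus (IFOF), thalamic radiation (TR), forceps minor of the corpus
callosum (CFMe), cingulum-hippocampus (CH), inferior longitudinal fasciculus
(ILF) and uncinate fasciculus (Un).  All are bilateral except the CFMe, a
midline commissural bundle.  Each tract is profiled at 100 equally spaced
nodes and partitioned into 5 segments of 20 consecutive nodes.
"""

from __future__ import annotations

TRACTS: tuple[str, ...] = ("IFOF", "TR", "CFMe", "CH", "ILF", "Un")
MIDLINE_TRACT = "CFMe"
BILATERAL_TRACTS: tuple[str, ...] = tuple(t for t in TRACTS if t != MIDLINE_TRACT)

#: Node-wise scalar variables (profiled at every node).
SCALAR_VARIABLES: tuple[str, ...] = ("FA", "MD", "Vol")
#: All quantitative variables; Fib (streamline count) is global-only.
ALL_VARIABLES: tuple[str, ...] = ("FA", "MD", "Vol", "Fib")

GROUPS: tuple[str, ...] = ("control", "FLE", "TLE")
PATIENT_GROUPS: tuple[str, ...] = ("FLE", "TLE")
SIDES: tuple[str, ...] = ("left", "right")
TIMEPOINTS: tuple[str, ...] = ("pre", "post")
ENGEL_CLASSES: tuple[str, ...] = ("I", "II", "III", "IV")

N_NODES = 100
N_SEGMENTS = 5


def segment_slice(segment: int, n_nodes: int = N_NODES,
                  n_segments: int = N_SEGMENTS) -> slice:
    """0-based slice of nodes covered by 1-based ``segment``.

    Segment k covers nodes (k-1)*w+1 .. k*w inclusive (1-based), w = n_nodes
    / n_segments; with the defaults, segment 3 is nodes 41-60.
    """
    from .errors import ConfigurationError

    if n_nodes % n_segments:
        raise ConfigurationError(
            f"n_nodes={n_nodes} not divisible by n_segments={n_segments}")
    if not 1 <= segment <= n_segments:
        raise ConfigurationError(
            f"segment={segment} outside 1..{n_segments}")
    width = n_nodes // n_segments
    return slice((segment - 1) * width, segment * width)


def tract_instances() -> list[tuple[str, str]]:
    """Analysis units after laterality recoding.

    Bilateral families contribute an ipsilateral and a contralateral
    instance; the CFMe contributes a single midline instance.  11 in total.
    """
    out: list[tuple[str, str]] = []
    for tract in TRACTS:
        if tract == MIDLINE_TRACT:
            out.append((tract, "midline"))
        else:
            out.append((tract, "ipsi"))
            out.append((tract, "contra"))
    return out
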