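"""Rebuild the bundled default structural-alphabet parameter set.

The default set shipped in ``saqc/data/default_alphabet.txt`` is calibrated
on a deterministic synthetic backbone corpus: 150 chains of 60 residues with
randomized helix/strand/coil segment plans, each paired with a
dihedral-jittered variant (sd 7°) so that the helix and strand basins are
populated with realistic spread. The fit is fully seeded; rerunning this
script reproduces the file byte for byte.

Usage:  python scripts/build_default_alphabet.py [OUT_PATH]
"""

import sys
from pathlib import Path

import numpy as np

from saqc import alphabet, synthetic
from saqc.io_structures import extract_ca_trace

N_CHAINS = 150
CHAIN_LENGTH = 60
JITTER_SD = 7.0
FIT_SEED = 0
VERSION = "saqc-default-1.0"


def random_segments(rng: np.random.Generator, n_residues: int):
    kinds = ["helix", "strand", "coil"]
    segments = []
    remaining = n_residues
    while remaining > 0:
        length = int(min(remaining, rng.integers(5, 16)))
        kind = kinds[int(rng.integers(0, 3))]
        segments.append((kind, length))
        remaining -= length
    return segments


def window_classes(segments):
    """Stratum of each 4-residue window, from the known segment plan.

    A window wholly inside a helix (resp. strand) segment is a helix
    (strand) window; everything else — coil or segment-straddling — is
    'other'.
    """
    per_residue = []
    for kind, length in segments:
        per_residue.extend([kind] * length)
    classes = []
    for i in range(len(per_residue) - 3):
        kinds = set(per_residue[i:i + 4])
        if kinds == {"helix"}:
            classes.append("helix")
        elif kinds == {"strand"}:
            classes.append("strand")
        else:
            classes.append("other")
    return classes


def build_corpus():
    traces = []
    classes = []
    for i in range(N_CHAINS):
        rng = np.random.default_rng(1000 + i)
        segments = random_segments(rng, CHAIN_LENGTH)
        spec = synthetic.BuildSpec(
            n_residues=CHAIN_LENGTH, segments=segments, seed=1000 + i
        )
        model = synthetic.build_chain(spec)
        traces.append(extract_ca_trace(model, "A"))
        classes.append(window_classes(segments))
        jittered = synthetic.build_ensemble(model, 1, JITTER_SD, seed=2000 + i)[0]
        traces.append(extract_ca_trace(jittered, "A"))
        classes.append(window_classes(segments))
    return traces, classes


def main():
    out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).resolve().parents[1] / "src/saqc/data/default_alphabet.txt"
    )
    traces, classes = build_corpus()
    params = alphabet.fit_alphabet(
        traces, seed=FIT_SEED, with_transitions=False, version=VERSION,
        window_classes=classes,
    )
    alphabet.save_parameters(params, out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
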