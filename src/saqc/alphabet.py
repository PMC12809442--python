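"""27-letter structural alphabet over four-Cα backbone fragments.

A chain's Cα trace is cut into overlapping windows of four consecutive Cα
atoms. Each window is reduced to four geometric descriptors:

* ``d1`` — distance Cα(i)–Cα(i+2),
* ``d2`` — distance Cα(i)–Cα(i+3),
* ``d3`` — distance Cα(i+1)–Cα(i+3),
* ``h``  — signed distance of Cα(i+3) from the plane of the first three Cα
  atoms (right-handed positive), which carries the chirality of the fragment.

Each window is then assigned one of 27 letters (labelled A–Z plus lowercase
a) by maximising either the Gaussian emission density of the letter alone
(``emission_only``) or the joint hidden-Markov path including letter-to-letter
transitions (``viterbi``). The letter of window (i..i+3) is stored on residue
i+2, so a gap-free chain of k residues yields exactly k−3 letters; windows
crossing a chain break stay unassigned.

This is a reimplementation of the structural-alphabet construction of
Camproux et al. (2004), not a bit-compatible port: the original published
parameters are not redistributed, and the bundled default set is calibrated
on a synthetic backbone corpus (see ``fit_alphabet`` and
``scripts/build_default_alphabet.py``). Letters of a re-fitted set are
aligned to the canonical secondary-structure classes by matching descriptor
means to ideal helix/strand archetypes, preserving the conventional class map
{A, a, V, W} → helix and {L, M, N, T, X} → strand.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_structures import CaTrace, ResKey

#: letter used for positions without a complete gap-free window
UNASSIGNED = "-"

CANONICAL_LETTERS = [
    "A", "a", "V", "W",                       # helix class
    "L", "M", "N", "T", "X",                  # strand class
    "B", "C", "D", "E", "F", "G", "H", "I", "J",
    "K", "O", "P", "Q", "R", "S", "U", "Y", "Z",
]
HELIX_LETTERS = ("A", "a", "V", "W")
STRAND_LETTERS = ("L", "M", "N", "T", "X")

DEFAULT_SS_CLASS = {
    letter: ("helix" if letter in HELIX_LETTERS
             else "strand" if letter in STRAND_LETTERS
             else "other")
    for letter in CANONICAL_LETTERS
}


class AlphabetError(ValueError):
    """Invalid alphabet parameters or parameter file."""


@dataclasses.dataclass
class FragmentDescriptors:
    d1: float
    d2: float
    d3: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3, self.h])


@dataclasses.dataclass
class AlphabetParameters:
    """Gaussian emission model (+ optional transitions) for the 27 letters."""

    letters: List[str]
    means: np.ndarray            # (27, 4)
    covariances: np.ndarray      # (27, 4, 4)
    transitions: Optional[np.ndarray] = None   # (27, 27), row-stochastic
    ss_class: Dict[str, str] = dataclasses.field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        n = len(self.letters)
        if n != 27:
            raise AlphabetError(f"expected 27 letters, got {n}")
        if len(set(self.letters)) != n:
            raise AlphabetError("duplicate letters")
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.means.shape != (n, 4) or self.covariances.shape != (n, 4, 4):
            raise AlphabetError("means/covariances have wrong shape")
        for i, cov in enumerate(self.covariances):
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise AlphabetError(
                    f"covariance of letter {self.letters[i]!r} not positive definite"
                ) from exc
        if self.transitions is not None:
            self.transitions = np.asarray(self.transitions, dtype=float)
            if self.transitions.shape != (n, n):
                raise AlphabetError("transition matrix has wrong shape")
            if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
                raise AlphabetError("transition rows must sum to 1")
        if not self.ss_class:
            self.ss_class = dict(DEFAULT_SS_CLASS)
        missing = set(self.letters) - set(self.ss_class)
        if missing:
            raise AlphabetError(f"ss_class map missing letters: {sorted(missing)}")
        self._index = {letter: i for i, letter in enumerate(self.letters)}
        self._chol = [np.linalg.cholesky(c) for c in self.covariances]
        self._log_norm = np.array([
            -0.5 * 4 * np.log(2 * np.pi) - np.log(np.diag(ch)).sum()
            for ch in self._chol
        ])

    def log_emission(self, descriptors: np.ndarray) -> np.ndarray:
        """Log Gaussian density of each letter for each row of descriptors.

        Parameters: descriptors (n, 4). Returns (n, 27).
        """
        from scipy.linalg import solve_triangular

        x = np.atleast_2d(np.asarray(descriptors, dtype=float))
        out = np.empty((x.shape[0], len(self.letters)))
        for j in range(len(self.letters)):
            diff = x - self.means[j]
            z = solve_triangular(self._chol[j], diff.T, lower=True)
            out[:, j] = self._log_norm[j] - 0.5 * np.sum(z * z, axis=0)
        return out


@dataclasses.dataclass
class LetterSequence:
    """Per-residue structural letters of one chain.

    ``entries`` are (res_key, one-letter amino acid, letter); the letter is
    :data:`UNASSIGNED` where no complete gap-free window exists.
    """

    chain_id: str
    entries: List[Tuple[ResKey, str, str]]

    def letters(self) -> Dict[ResKey, str]:
        return {key: letter for key, _, letter in self.entries}

    def assigned(self) -> List[Tuple[ResKey, str]]:
        return [(key, letter) for key, _, letter in self.entries
                if letter != UNASSIGNED]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# descriptors


def fragment_descriptors(window: np.ndarray) -> FragmentDescriptors:
    """Geometric descriptors of a window of four Cα coordinates.

    ``h`` is zero when the first three points are collinear (the plane is
    undefined; measure-zero case).
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (4, 3):
        raise ValueError(f"window must be 4x3, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite coordinates in window")
    d1 = float(np.linalg.norm(w[2] - w[0]))
    d2 = float(np.linalg.norm(w[3] - w[0]))
    d3 = float(np.linalg.norm(w[3] - w[1]))
    normal = np.cross(w[1] - w[0], w[2] - w[0])
    norm = np.linalg.norm(normal)
    if norm < 1e-10:
        h = 0.0
    else:
        h = float(np.dot(w[3] - w[0], normal / norm))
    return FragmentDescriptors(d1, d2, d3, h)


def trace_descriptors(trace: CaTrace) -> Tuple[np.ndarray, List[List[int]]]:
    """Descriptors of every gap-free window of a trace.

    Returns (descriptor array, window index lists per gap-free segment). The
    window starting at trace position i covers positions i..i+3 and its
    letter is reported on position i+2.
    """
    coords = trace.coords()
    rows = []
    window_segments: List[List[int]] = []
    for seg in trace.segments():
        seg_windows = []
        for j in range(len(seg) - 3):
            i = seg[j]
            rows.append(fragment_descriptors(coords[i:i + 4]).as_array())
            seg_windows.append(i)
        if seg_windows:
            window_segments.append(seg_windows)
    if rows:
        return np.array(rows), window_segments
    return np.empty((0, 4)), window_segments


# ---------------------------------------------------------------------------
# encoding


def encode(trace: CaTrace, params: AlphabetParameters, mode: str = "auto") -> LetterSequence:
    """Encode a Cα trace into a structural-letter sequence.

    ``mode`` is ``emission_only``, ``viterbi``, or ``auto`` (viterbi when the
    parameter set carries transitions, emission_only otherwise).
    """
    if mode == "auto":
        mode = "viterbi" if params.transitions is not None else "emission_only"
    if mode not in ("emission_only", "viterbi"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "viterbi" and params.transitions is None:
        raise AlphabetError("viterbi mode requires a transition matrix")

    desc, window_segments = trace_descriptors(trace)
    letters = [UNASSIGNED] * len(trace)
    if len(desc):
        log_em = params.log_emission(desc)
        row = 0
        for seg_windows in window_segments:
            k = len(seg_windows)
            seg_em = log_em[row:row + k]
            row += k
            if mode == "emission_only":
                states = np.argmax(seg_em, axis=1)
            else:
                states = _viterbi(seg_em, np.log(params.transitions + 1e-300))
            for start, s in zip(seg_windows, states):
                letters[start + 2] = params.letters[s]
    entries = [
        (pos.res_key, pos.aa, letters[i])
        for i, pos in enumerate(trace.positions)
    ]
    return LetterSequence(trace.chain_id, entries)


def _viterbi(log_em: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    n, k = log_em.shape
    delta = log_em[0].copy()  # uniform initial distribution (constant offset)
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(k)] + log_em[t]
    states = np.zeros(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def ss_class(letter: str, params: AlphabetParameters) -> str:
    """Secondary-structure class (helix/strand/other) of a letter."""
    if letter not in params.ss_class:
        raise KeyError(f"unknown structural letter {letter!r}")
    return params.ss_class[letter]


# ---------------------------------------------------------------------------
# parameter file IO (plain-text, sections, '#' comments, Å units)


def save_parameters(params: AlphabetParameters, path: str | Path) -> None:
    lines = ["# saqc structural-alphabet parameters", f"version = {params.version}", ""]
    lines.append("[letters]")
    lines.append(" ".join(params.letters))
    lines.append("")
    lines.append("[emission]")
    lines.append("# letter  mean(d1 d2 d3 h)  covariance upper triangle (row-major)")
    iu = np.triu_indices(4)
    for i, letter in enumerate(params.letters):
        mean = " ".join(f"{v:.6f}" for v in params.means[i])
        cov = " ".join(f"{v:.6f}" for v in params.covariances[i][iu])
        lines.append(f"{letter} {mean} {cov}")
    if params.transitions is not None:
        lines.append("")
        lines.append("[transitions]")
        for i, letter in enumerate(params.letters):
            row = " ".join(f"{v:.6e}" for v in params.transitions[i])
            lines.append(f"{letter} {row}")
    lines.append("")
    lines.append("[ss_class]")
    for letter in params.letters:
        lines.append(f"{letter} {params.ss_class[letter]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_parameters(path: str | Path) -> AlphabetParameters:
    text = Path(path).read_text()
    return _parse_parameters(text)


def _parse_parameters(text: str) -> AlphabetParameters:
    section = None
    version = "unversioned"
    letters: List[str] = []
    emission: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    transitions: Dict[str, np.ndarray] = {}
    ss_map: Dict[str, str] = {}
    iu = np.triu_indices(4)
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            continue
        if section is None:
            if "=" in line:
                key, _, value = line.partition("=")
                if key.strip() == "version":
                    version = value.strip()
            continue
        if section == "letters":
            letters.extend(line.split())
        elif section == "emission":
            tokens = line.split()
            if len(tokens) != 15:
                raise AlphabetError(f"bad emission line: {raw!r}")
            letter = tokens[0]
            values = np.array([float(t) for t in tokens[1:]])
            cov = np.zeros((4, 4))
            cov[iu] = values[4:]
            cov = cov + np.triu(cov, 1).T
            emission[letter] = (values[:4], cov)
        elif section == "transitions":
            tokens = line.split()
            if len(tokens) != 28:
                raise AlphabetError(f"bad transition line: {raw!r}")
            transitions[tokens[0]] = np.array([float(t) for t in tokens[1:]])
        elif section == "ss_class":
            letter, cls = line.split()
            if cls not in ("helix", "strand", "other"):
                raise AlphabetError(f"unknown secondary-structure class {cls!r}")
            ss_map[letter] = cls
        else:
            raise AlphabetError(f"unknown section [{section}]")
    if len(letters) != 27:
        raise AlphabetError(f"parameter file lists {len(letters)} letters, expected 27")
    missing = [l for l in letters if l not in emission]
    if missing:
        raise AlphabetError(f"emission parameters missing for letters: {missing}")
    means = np.array([emission[l][0] for l in letters])
    covs = np.array([emission[l][1] for l in letters])
    trans = None
    if transitions:
        if set(transitions) != set(letters):
            raise AlphabetError("transition section does not cover all letters")
        trans = np.array([transitions[l] for l in letters])
    return AlphabetParameters(letters, means, covs, trans, ss_map, version)


_DEFAULT_CACHE: Optional[AlphabetParameters] = None


def default_parameters() -> AlphabetParameters:
    """The bundled default 27-letter parameter set."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        text = resources.files("saqc.data").joinpath("default_alphabet.txt").read_text()
        _DEFAULT_CACHE = _parse_parameters(text)
    return _DEFAULT_CACHE


# ---------------------------------------------------------------------------
# calibration


def _archetype_descriptors() -> Tuple[np.ndarray, np.ndarray]:
    """Descriptor means of ideal helix and strand windows."""
    from . import synthetic
    from .io_structures import extract_ca_trace

    helix = synthetic.helix_trace(12)
    strand = synthetic.build_chain(
        synthetic.BuildSpec(n_residues=12, segments=[("strand", 12)])
    )
    strand_trace = extract_ca_trace(strand, "A")
    helix_desc, _ = trace_descriptors(helix)
    strand_desc, _ = trace_descriptors(strand_trace)
    return helix_desc.mean(axis=0), strand_desc.mean(axis=0)


#: canonical class composition of the 27-letter alphabet
CLASS_COMPOSITION = {"helix": 4, "strand": 5, "other": 18}
#: descriptor-distance cutoff (Å) for auto-assigning windows to a regular class
ARCHETYPE_CUTOFF = 1.2


def fit_alphabet(
    traces: Iterable[CaTrace],
    seed: int = 0,
    with_transitions: bool = True,
    version: str = "fitted",
    min_cov_jitter: float = 2.5e-3,
    window_classes: Optional[Sequence[Sequence[str]]] = None,
) -> AlphabetParameters:
    """Calibrate a 27-letter parameter set from a structure corpus.

    Calibration is stratified to reproduce the canonical class composition
    of the alphabet — 4 helix letters, 5 strand letters, 18 others: fragment
    descriptors harvested from all gap-free windows of ``traces`` are first
    partitioned into helix/strand/other strata, then each stratum is
    clustered with seeded k-means into its fixed number of letters. Without
    stratification a single k-means over all windows concentrates letters
    wherever the corpus has most spread, which loses the fine granularity
    within the regular secondary-structure basins that the alphabet needs to
    resolve small backbone adjustments.

    ``window_classes``, when given, supplies the stratum of every window of
    every trace (one sequence of ``helix``/``strand``/``other`` labels per
    trace, in window order — corpus generators that know their segment plans
    can provide exact labels). Otherwise windows within
    :data:`ARCHETYPE_CUTOFF` of the ideal helix or strand archetype
    descriptors are assigned to that stratum.

    Each cluster yields a Gaussian emission (empirical covariance plus an
    isotropic jitter floor for numerical stability); transitions are
    estimated from consecutive window labels with Laplace smoothing. Within
    the helix stratum the largest cluster becomes A (the canonical helix
    letter), then a, V, W by decreasing size; strand clusters become
    L, M, N, T, X the same way; the remaining letters are assigned by
    ascending mean d2.
    """
    from sklearn.cluster import KMeans

    desc_blocks = []
    class_blocks = []
    segment_rows: List[int] = []  # number of consecutive windows per segment
    for t_idx, trace in enumerate(traces):
        desc, window_segments = trace_descriptors(trace)
        if len(desc) == 0:
            continue
        desc_blocks.append(desc)
        segment_rows.extend(len(s) for s in window_segments)
        if window_classes is not None:
            labels = list(window_classes[t_idx])
            if len(labels) != len(desc):
                raise AlphabetError(
                    f"window_classes[{t_idx}] has {len(labels)} labels for "
                    f"{len(desc)} windows"
                )
            class_blocks.append(labels)
    if not desc_blocks:
        raise AlphabetError("no complete windows in the training traces")
    data = np.vstack(desc_blocks)
    if len(data) < 27 * 4:
        raise AlphabetError(f"too few windows ({len(data)}) to fit 27 letters")

    helix_arch, strand_arch = _archetype_descriptors()
    if window_classes is not None:
        strata = np.array([c for block in class_blocks for c in block])
        if not set(strata) <= {"helix", "strand", "other"}:
            raise AlphabetError("window classes must be helix/strand/other")
    else:
        d_helix = np.linalg.norm(data - helix_arch, axis=1)
        d_strand = np.linalg.norm(data - strand_arch, axis=1)
        strata = np.full(len(data), "other", dtype=object)
        strata[(d_helix < ARCHETYPE_CUTOFF) & (d_helix <= d_strand)] = "helix"
        strata[(d_strand < ARCHETYPE_CUTOFF) & (d_strand < d_helix)] = "strand"

    class_letters = {
        "helix": list(HELIX_LETTERS),
        "strand": list(STRAND_LETTERS),
        "other": [l for l in CANONICAL_LETTERS
                  if l not in HELIX_LETTERS + STRAND_LETTERS],
    }
    means = np.empty((27, 4))
    covs = np.empty((27, 4, 4))
    letter_index = {letter: i for i, letter in enumerate(CANONICAL_LETTERS)}
    window_letter = np.empty(len(data), dtype=int)  # canonical letter index
    for cls, k in CLASS_COMPOSITION.items():
        members = np.where(strata == cls)[0]
        if len(members) < 4 * k:
            raise AlphabetError(
                f"too few {cls} windows ({len(members)}) to fit {k} letters"
            )
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(data[members])
        sizes = np.bincount(labels, minlength=k)
        if cls == "other":
            order = np.argsort(km.cluster_centers_[:, 1])  # ascending mean d2
        else:
            order = np.argsort(-sizes)                     # largest first
        for slot, cluster in enumerate(order):
            letter = class_letters[cls][slot]
            idx = letter_index[letter]
            sub = data[members][labels == cluster]
            means[idx] = km.cluster_centers_[cluster]
            cov = np.cov(sub.T) if len(sub) > 4 else np.eye(4) * 0.25
            covs[idx] = cov + min_cov_jitter * np.eye(4)
            window_letter[members[labels == cluster]] = idx

    trans = None
    if with_transitions:
        counts = np.ones((27, 27))  # Laplace smoothing
        row = 0
        for n_windows in segment_rows:
            seg_states = window_letter[row:row + n_windows]
            row += n_windows
            for a, b in zip(seg_states[:-1], seg_states[1:]):
                counts[a, b] += 1
        trans = counts / counts.sum(axis=1, keepdims=True)

    return AlphabetParameters(
        list(CANONICAL_LETTERS), means, covs, trans, dict(DEFAULT_SS_CLASS), version
    )
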