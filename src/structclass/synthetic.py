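"""Synthetic class-labelled domains: secondary structure, sequence, PSSM.

Each structural class is emulated by a block grammar over the four
secondary-structure codes:

* all-alpha  — helix blocks (6-20 residues) separated by short coils;
* all-beta   — anti-parallel sheet blocks (3-10) separated by coils;
* alpha/beta — alternating helix and parallel-sheet blocks (the
  interspersed architecture);
* alpha+beta — a helical region followed by an anti-parallel sheet
  region (the segregated architecture).

Sequences are drawn from element-conditioned amino-acid propensity
tables (helix formers over H; beta-branched hydrophobics over parallel
sheets; aromatics/polar beta residues over anti-parallel sheets; turn
formers over coil), and integer log-odds profiles are built around the
drawn residue with positive scores for its element's propensity group,
Gaussian noise, and clipping to the [-10, 13] range of real PSI-BLAST
output.  The class signal is therefore linear in composition-type
features, which is what the regression is designed to recover; no
attempt is made to mimic PSI-BLAST iteration effects or real
evolutionary profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io
from .features import extract_features
from .model import DomainDataset
from .scales import PSSM_COLUMNS
from .targets import CLASSES

__all__ = [
    "SimulationConfig",
    "PROPENSITY_GROUPS",
    "simulate_ss",
    "simulate_sequence",
    "simulate_pssm",
    "simulate_domain",
    "simulate_dataset",
    "write_dataset_dir",
]

#: Residues favoured by each secondary-structure element.  Parallel and
#: anti-parallel sheets get distinct groups (buried beta-branched
#: hydrophobics vs edge-tolerant aromatics/polar) so the two sheet
#: topologies leave distinct sequence signals.
PROPENSITY_GROUPS: dict[str, str] = {
    "H": "AELMQK",
    "P": "VICLF",
    "A": "TYWSF",
    "C": "GPNDS",
}

#: Boost factor for favoured residues in the sequence propensity tables.
_PROPENSITY_BOOST = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    200 domains per class with lengths uniform on [60, 300] residues
    (domains shorter than 30 residues never occur, mirroring the usual
    dataset filter), unit PSSM noise and unit signal strength.
    """

    n_per_class: int = 200
    length_range: tuple[int, int] = (60, 300)
    pssm_noise_sd: float = 1.0
    signal_strength: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.length_range[0] < 30:
            raise ValueError("minimum domain length is 30 residues")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")


def _blocks(rng, L, element, elem_lo, elem_hi, coil_lo=2, coil_hi=8):
    parts = []
    total = 0
    while total < L:
        blen = int(rng.integers(elem_lo, elem_hi + 1))
        parts.append(element * blen)
        total += blen
        clen = int(rng.integers(coil_lo, coil_hi + 1))
        parts.append("C" * clen)
        total += clen
    return "".join(parts)[:L]


def simulate_ss(class_label: str, L: int, rng: np.random.Generator) -> str:
    """Draw a length-L secondary-structure string from the class grammar."""
    if L < 30:
        raise ValueError("domain length must be at least 30")
    if class_label == "all-alpha":
        return _blocks(rng, L, "H", 6, 20)
    if class_label == "all-beta":
        return _blocks(rng, L, "A", 3, 10)
    if class_label == "alpha/beta":
        parts, total, use_helix = [], 0, True
        while total < L:
            if use_helix:
                blen = int(rng.integers(6, 16))
                parts.append("H" * blen)
            else:
                blen = int(rng.integers(3, 9))
                parts.append("P" * blen)
            total += blen
            clen = int(rng.integers(1, 5))
            parts.append("C" * clen)
            total += clen
            use_helix = not use_helix
        return "".join(parts)[:L]
    if class_label == "alpha+beta":
        split = L // 2
        helical = _blocks(rng, split, "H", 6, 20)
        sheet = _blocks(rng, L - split, "A", 3, 10)
        return helical + sheet
    raise ValueError(f"unknown class {class_label!r}")


def _propensity_table(element: str) -> np.ndarray:
    p = np.ones(20)
    for a in PROPENSITY_GROUPS[element]:
        p[PSSM_COLUMNS.index(a)] *= _PROPENSITY_BOOST
    return p / p.sum()


_TABLES = {e: _propensity_table(e) for e in "HAPC"}


def simulate_sequence(ss: str, rng: np.random.Generator) -> str:
    """Draw a sequence from element-conditioned residue propensities."""
    aas = np.array(list(PSSM_COLUMNS))
    return "".join(
        aas[rng.choice(20, p=_TABLES[element])] for element in ss
    )


def simulate_pssm(
    sequence: str,
    ss: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> io.PSSM:
    """Integer log-odds profile with a planted, element-linked signal.

    Per position: the drawn residue scores about +4, residues in its
    element's propensity group score mildly positive, all others
    negative; Gaussian noise of sd ``pssm_noise_sd`` is added before
    rounding and clipping to [-10, 13].
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if len(sequence) != len(ss):
        raise ValueError("sequence and secondary structure differ in length")
    L = len(sequence)
    base = np.full((L, 20), -2.0)
    s = config.signal_strength
    for i, (res, element) in enumerate(zip(sequence, ss)):
        for a in PROPENSITY_GROUPS[element]:
            base[i, PSSM_COLUMNS.index(a)] = 2.0 * s
        if res in PSSM_COLUMNS:
            base[i, PSSM_COLUMNS.index(res)] = 4.0
    noisy = base + rng.normal(0.0, config.pssm_noise_sd, size=(L, 20))
    scores = np.clip(np.rint(noisy), -10, 13).astype(int)
    return io.PSSM(sequence, scores)


def simulate_domain(class_label, L, config, rng):
    """One domain: (ss, sequence, pssm, 440D features)."""
    ss = simulate_ss(class_label, L, rng)
    seq = simulate_sequence(ss, rng)
    pssm = simulate_pssm(seq, ss, config, rng)
    return ss, seq, pssm, extract_features(seq, pssm)


def simulate_dataset(
    config: SimulationConfig | None = None, keep_raw: bool = False
):
    """Simulate ``n_per_class`` domains per class, split 80/20 stratified.

    Returns ``(train, test)`` :class:`DomainDataset` objects; with
    ``keep_raw`` also a dict of domain_id -> (sequence, pssm) for file
    output.  Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    ids, X, ss_list, labels = [], [], [], []
    raw = {}
    for cls_i, cls in enumerate(CLASSES):
        for j in range(config.n_per_class):
            L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            ss, seq, pssm, feats = simulate_domain(cls, L, config, rng)
            did = f"syn{cls_i}_{j:04d}"
            ids.append(did)
            X.append(feats)
            ss_list.append(ss)
            labels.append(cls)
            if keep_raw:
                raw[did] = (seq, pssm)
    X = np.array(X)
    n_train = int(round(0.8 * config.n_per_class))
    train_idx, test_idx = [], []
    for cls_i in range(len(CLASSES)):
        block = np.arange(cls_i * config.n_per_class, (cls_i + 1) * config.n_per_class)
        perm = rng.permutation(block)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    full = DomainDataset(ids, X, ss_list, labels)
    train, test = full.subset(np.array(train_idx)), full.subset(np.array(test_idx))
    if keep_raw:
        return train, test, raw
    return train, test


def write_dataset_dir(config: SimulationConfig, out_dir) -> None:
    """Materialise a simulated dataset in the external file formats.

    Writes ``sequences.fasta``, one ASCII PSSM per domain under
    ``pssm/``, ``domains.tsv``, ``labels.tsv``, ``ss.tsv`` and
    ``features.tsv`` (train and test prefixed separately).
    """
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    train, test, raw = simulate_dataset(config, keep_raw=True)
    for prefix, ds in (("train", train), ("test", test)):
        records = [io.SequenceRecord(i, raw[i][0]) for i in ds.ids]
        io.write_fasta(records, out / f"{prefix}_sequences.fasta")
        for did in ds.ids:
            io.write_pssm(raw[did][1], out / "pssm" / f"{did}.pssm")
        intervals = [
            io.DomainInterval(did, did, 1, len(raw[did][0]), lab)
            for did, lab in zip(ds.ids, ds.labels)
        ]
        io.write_domain_table(intervals, out / f"{prefix}_domains.tsv")
        io.write_labels(dict(zip(ds.ids, ds.labels)), out / f"{prefix}_labels.tsv")
        io.write_ss_table(dict(zip(ds.ids, ds.ss)), out / f"{prefix}_ss.tsv")
        io.write_feature_table(ds.ids, ds.X, out / f"{prefix}_features.tsv")
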