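"""96-channel trinucleotide conventions and the signature catalog.

Single-base substitutions are standardized to the pyrimidine strand,
giving six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each
with 16 flanking-base contexts: 96 channels in the conventional
catalog order (class-major, then 5' base, then 3' base, A<C<G<T).

The packaged catalog (``data/signature_catalog_synthetic.tsv``) is a
deterministic synthetic stand-in for the 30-signature COSMIC v2
catalog: same shape, channel order and column naming, with the
signatures that matter downstream (1, 2, 3, 6, 13, 22, 29) given
profiles that mimic their published character (e.g. signature 1
concentrated at N[C>T]G, APOBEC signatures at T[C>N]N, signature 3
near-uniform).  It is NOT the COSMIC catalog; swap in the real one
via ``load_catalog(path)`` for production use.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

N_SIGNATURES = 30
SIGNATURE_NAMES = tuple(f"Signature {i}" for i in range(1, N_SIGNATURES + 1))


def _channels() -> list[str]:
    out = []
    for sub in SUBSTITUTION_CLASSES:
        for five in BASES:
            for three in BASES:
                out.append(f"{five}[{sub}]{three}")
    return out


CHANNELS_96: tuple[str, ...] = tuple(_channels())
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def standardize_substitution(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Return (substitution class, standardized trinucleotide context).

    Purine-centered substitutions are mapped to the reverse-complement
    (pyrimidine) strand, so e.g. a G>T in context AGC becomes C>A in
    GCT.  The context middle base must equal ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"malformed substitution {ref}>{alt} context {context!r}")
    if any(b not in COMPLEMENT for b in context) or alt not in COMPLEMENT:
        raise ValueError(f"non-ACGT base in {ref}>{alt} {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]} != ref {ref}")
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = reverse_complement(context)
    return f"{ref}>{alt}", context


def channel_of(ref: str, alt: str, context: str) -> int:
    """96-channel index of a substitution in its trinucleotide context."""
    sub, ctx = standardize_substitution(ref, alt, context)
    return _CHANNEL_INDEX[f"{ctx[0]}[{sub}]{ctx[2]}"]


def _peaked(rng: np.random.Generator, channels: np.ndarray, weight: float) -> np.ndarray:
    """Profile putting ``weight`` mass on ``channels``, rest diffuse."""
    p = rng.dirichlet(np.full(96, 0.08))
    focus = rng.dirichlet(np.full(len(channels), 1.0))
    out = (1.0 - weight) * p
    out[channels] += weight * focus
    return out


def _class_channels(sub: str, five: str | None = None, three: str | None = None) -> np.ndarray:
    idx = []
    for i, ch in enumerate(CHANNELS_96):
        if f"[{sub}]" not in ch:
            continue
        if five is not None and ch[0] != five:
            continue
        if three is not None and ch[-1] != three:
            continue
        idx.append(i)
    return np.asarray(idx)


def synthetic_catalog() -> pd.DataFrame:
    """Deterministically generate the synthetic 96x30 catalog.

    Columns sum to 1.  Regenerating always yields the shipped TSV.
    """
    rng = np.random.default_rng(96 * 30)
    cols = {}
    structured = {
        # aging-like: C>T at NpCpG
        "Signature 1": _peaked(rng, _class_channels("C>T", three="G"), 0.85),
        # APOBEC-like: C>T at TpCpN
        "Signature 2": _peaked(rng, _class_channels("C>T", five="T"), 0.85),
        # HR-deficiency-like: near-uniform
        "Signature 3": rng.dirichlet(np.full(96, 60.0)),
        # MMR-deficiency-like: broad C>T
        "Signature 6": _peaked(rng, _class_channels("C>T"), 0.75),
        # APOBEC-like: C>G at TpCpN
        "Signature 13": _peaked(rng, _class_channels("C>G", five="T"), 0.85),
        # aristolochic-acid-like: T>A
        "Signature 22": _peaked(rng, _class_channels("T>A"), 0.9),
        # tobacco-chewing-like: C>A
        "Signature 29": _peaked(rng, _class_channels("C>A"), 0.8),
    }
    for name in SIGNATURE_NAMES:
        if name in structured:
            cols[name] = structured[name]
        else:
            cols[name] = rng.dirichlet(np.full(96, 0.15))
    cat = pd.DataFrame(cols, index=list(CHANNELS_96))
    return cat / cat.sum(axis=0)


def load_catalog(path=None) -> pd.DataFrame:
    """Load a 96x30 signature catalog TSV (default: packaged synthetic one)."""
    if path is None:
        ref = importlib.resources.files("escc_ith.data").joinpath(
            "signature_catalog_synthetic.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            cat = pd.read_csv(p, sep="\t", index_col=0)
    else:
        cat = pd.read_csv(path, sep="\t", index_col=0)
    if list(cat.index) != list(CHANNELS_96):
        raise ValueError("catalog rows must be the 96 channels in standard order")
    sums = cat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("catalog columns must each sum to 1")
    return cat
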