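"""Assembly of the full 612-dimensional feature vector and batch encoding.

Block order is fixed: k-gram (84) | MMI (30) | DWT (312) | PseAAC (186).
Features are stored raw; standardisation happens inside the classifier so
saved feature tables are reproducible and classifier-agnostic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import dwt as dwt_mod
from . import kgram as kgram_mod
from . import mmi as mmi_mod
from . import pseaac as pseaac_mod
from .errors import DataError, MethylpredError
from .physchem import build_pc_matrix, load_property_table


@dataclass(frozen=True)
class FeatureConfig:
    """Extractor settings; echoed into every saved feature table header."""

    wavelet: str = dwt_mod.DEFAULT_WAVELET
    padding_mode: str = dwt_mod.DEFAULT_MODE
    dwt_levels: int = dwt_mod.DEFAULT_LEVELS
    lambda_max: int = pseaac_mod.DEFAULT_LAMBDA_MAX
    normalize_kgram: bool = False
    property_table_path: str | None = None


@dataclass(frozen=True)
class BlockSpec:
    name: str
    start: int
    length: int


def block_ledger(config: FeatureConfig | None = None) -> tuple[BlockSpec, ...]:
    config = config or FeatureConfig()
    dims = (
        ("kgram", kgram_mod.KGRAM_DIM),
        ("mmi", mmi_mod.MMI_DIM),
        ("dwt", 6 * config.dwt_levels * dwt_mod.PER_LEVEL),
        ("pseaac", 6 * (config.lambda_max + 1)),
    )
    ledger, start = [], 0
    for name, dim in dims:
        ledger.append(BlockSpec(name, start, dim))
        start += dim
    return tuple(ledger)


def feature_names(config: FeatureConfig | None = None) -> tuple[str, ...]:
    """612 stable feature identifiers, prefixed by their block name."""
    config = config or FeatureConfig()
    names = [f"kgram_{n}" for n in kgram_mod.KGRAM_NAMES]
    names += [f"mmi_{n}" for n in mmi_mod.MMI_NAMES]
    names += [
        f"dwt_{prop}_L{level}_{slot}"
        for prop in dwt_mod.PROPERTY_NAMES
        for level in range(1, config.dwt_levels + 1)
        for slot in dwt_mod.SLOT_NAMES
    ]
    names += [f"pseaac_{n}" for n in pseaac_mod.pseaac_names(config.lambda_max)]
    return tuple(names)


TOTAL_DIM = len(feature_names())  # 612


def encode(sequence: str, config: FeatureConfig | None = None) -> np.ndarray:
    """Encode one window as the concatenated [kgram | mmi | dwt | pseaac] vector."""
    config = config or FeatureConfig()
    table = (
        load_property_table(config.property_table_path)
        if config.property_table_path
        else None
    )
    pc = build_pc_matrix(sequence, table=table)
    return np.concatenate(
        [
            kgram_mod.kgram_features(sequence, normalize=config.normalize_kgram),
            mmi_mod.mmi_features(sequence),
            dwt_mod.dwt_features(
                pc, levels=config.dwt_levels, wavelet=config.wavelet,
                mode=config.padding_mode,
            ),
            pseaac_mod.pseaac_features(pc, lambda_max=config.lambda_max),
        ]
    )


def encode_batch(
    records,
    config: FeatureConfig | None = None,
    skip_invalid: bool = False,
):
    """Encode a collection of labeled records into a feature table.

    Parameters
    ----------
    records
        Iterable of objects with ``identifier``, ``sequence``, ``label`` and
        optionally ``origin`` attributes (e.g. ``dataset.WindowRecord``), or
        plain (identifier, sequence, label) tuples.
    skip_invalid
        When True, records failing validation are dropped and reported
        instead of raising.

    Returns
    -------
    (features, labels, origins, skipped) where features is a DataFrame with
    feature-name columns indexed by record identifier, labels and origins are
    aligned Series, and skipped is a list of (identifier, reason) pairs.
    """
    config = config or FeatureConfig()
    rows, ids, labels, origins = [], [], [], []
    skipped: list[tuple[str, str]] = []
    n_seen = 0
    for rec in records:
        n_seen += 1
        if isinstance(rec, tuple):
            ident, seq, label = rec[:3]
            origin = "real"
        else:
            ident, seq, label = rec.identifier, rec.sequence, rec.label
            origin = getattr(rec, "origin", "real")
        try:
            rows.append(encode(seq, config=config))
        except MethylpredError as exc:
            if skip_invalid:
                skipped.append((ident, str(exc)))
                continue
            exc.args = (f"record {ident!r}: {exc}",)
            raise
        ids.append(ident)
        labels.append(label)
        origins.append(origin)
    if n_seen == 0:
        raise DataError("cannot encode an empty record collection")
    features = pd.DataFrame(np.array(rows), index=ids, columns=feature_names(config))
    return (
        features,
        pd.Series(labels, index=ids, name="label"),
        pd.Series(origins, index=ids, name="origin"),
        skipped,
    )


def write_feature_table(path, features: pd.DataFrame, labels=None, origins=None,
                        config: FeatureConfig | None = None) -> None:
    """Tab-separated export: comment header with the config, then the table."""
    config = config or FeatureConfig()
    df = features.copy()
    if labels is not None:
        df.insert(0, "label", labels)
    if origins is not None:
        df.insert(1, "origin", origins)
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index_label="identifier")


def read_feature_table(path):
    """Inverse of :func:`write_feature_table`.

    Returns (features, labels-or-None, origins-or-None, config_dict).
    """
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep="\t", index_col="identifier")
    labels = df.pop("label") if "label" in df.columns else None
    origins = df.pop("origin") if "origin" in df.columns else None
    return df, labels, origins, header
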