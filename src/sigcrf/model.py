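"""Encoder + CRF model container, prediction, and JSON serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from . import crf
from .crf import CrfParams, Prediction
from .encoder import EncoderParams, encode
from .grammar import StateSpace, build_state_space
from .types import OrganismGroup

FORMAT_VERSION = 1
GRAMMAR_VERSION = "sp-41state-v1"


@dataclass
class Model:
    """A trained predictor: encoder parameters, CRF parameters, grammar."""

    encoder: EncoderParams
    params: CrfParams
    space: StateSpace

    @classmethod
    def init(cls, seed: int = 0, emb_dim: int = 8, hidden_dim: int = 64,
             window_radius: int = 3) -> "Model":
        rng = np.random.default_rng(seed)
        space = build_state_space()
        enc = EncoderParams.init(rng, emb_dim=emb_dim, hidden_dim=hidden_dim,
                                 window_radius=window_radius)
        params = CrfParams.init(hidden_dim, space, rng)
        return cls(encoder=enc, params=params, space=space)


def predict(sequence: str, group: OrganismGroup, model: Model) -> Prediction:
    """Full prediction for one sequence: encoder -> emissions -> decode."""
    if not sequence:
        raise ValueError("empty sequence")
    hidden = encode(sequence, group, model.encoder)
    em = crf.emissions(hidden, model.params)
    return crf.decode(em, model.params, model.space)


def save_model(model: Model, path: Union[str, Path]) -> None:
    enc = model.encoder
    payload = {
        "format_version": FORMAT_VERSION,
        "grammar_version": GRAMMAR_VERSION,
        "encoder": {
            "emb": enc.emb.tolist(),
            "group_emb": enc.group_emb.tolist(),
            "bos": enc.bos.tolist(),
            "eos": enc.eos.tolist(),
            "W1": enc.W1.tolist(),
            "b1": enc.b1.tolist(),
            "window_radius": enc.window_radius,
            "emb_dim": enc.emb_dim,
            "hidden_dim": enc.hidden_dim,
        },
        "crf": {
            "W_psi": model.params.W_psi.tolist(),
            "b_psi": model.params.b_psi.tolist(),
            "phi": model.params.phi.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: Union[str, Path]) -> Model:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version: {payload.get('format_version')}"
        )
    if payload.get("grammar_version") != GRAMMAR_VERSION:
        raise ValueError(
            f"model built for grammar {payload.get('grammar_version')!r}, "
            f"expected {GRAMMAR_VERSION!r}"
        )
    e = payload["encoder"]
    enc = EncoderParams(
        emb=np.array(e["emb"]), group_emb=np.array(e["group_emb"]),
        bos=np.array(e["bos"]), eos=np.array(e["eos"]),
        W1=np.array(e["W1"]), b1=np.array(e["b1"]),
        window_radius=e["window_radius"], emb_dim=e["emb_dim"],
        hidden_dim=e["hidden_dim"],
    )
    c = payload["crf"]
    params = CrfParams(
        W_psi=np.array(c["W_psi"]), b_psi=np.array(c["b_psi"]),
        phi=np.array(c["phi"]),
    )
    return Model(encoder=enc, params=params, space=build_state_space())
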