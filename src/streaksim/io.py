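"""Output helpers: label snapshots, field renders, checkpoints."""

from __future__ import annotations

import json

import numpy as np
from PIL import Image

from .core import CELL_TYPE_NAMES, SimParams, TissueState

# fixed display colors per cell type (medium, AP, AO, S, ST)
_TYPE_RGB = np.array([[0, 0, 0], [200, 60, 60], [70, 170, 70],
                      [60, 80, 220], [240, 220, 60]], dtype=np.uint8)


def _id_colors(n: int) -> np.ndarray:
    """Deterministic distinct-ish RGB per cell id (id 0 = black)."""
    rng = np.random.default_rng(12345)
    colors = rng.integers(40, 256, size=(n, 3), dtype=np.uint8)
    colors[0] = 0
    return colors


def save_label_snapshot(state: TissueState, path, by: str = "id",
                        boundaries: bool = True) -> None:
    """PNG of the owner lattice, one color per cell id (or per type),
    with a plain-text id -> type legend beside it."""
    if by == "type":
        img = _TYPE_RGB[state.ctype[state.owner]]
    else:
        img = _id_colors(state.n_ids)[state.owner]
    if boundaries:
        edge = np.zeros(state.shape, dtype=bool)
        edge[:-1, :] |= state.owner[:-1, :] != state.owner[1:, :]
        edge[:, :-1] |= state.owner[:, :-1] != state.owner[:, 1:]
        img = img.copy()
        img[edge] //= 2
    Image.fromarray(img, mode="RGB").save(path)
    legend = "\n".join(
        f"{cid}\t{CELL_TYPE_NAMES[state.ctype[cid]]}"
        for cid in state.live_cells())
    with open(str(path) + ".legend.txt", "w") as fh:
        fh.write(f"# id\ttype (seed run step {state.step})\n" + legend + "\n")


def save_field_png(values: np.ndarray, path, vmax: float = 1.5) -> None:
    """Grayscale render, 0 -> black, ``vmax`` -> white."""
    img = np.clip(values / vmax, 0.0, 1.0)
    Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)


def save_checkpoint(path, state: TissueState, fields: dict | None = None) -> None:
    """Single-archive checkpoint (npz); round-trips exactly."""
    n = state.n_ids
    payload = {
        "owner": state.owner,
        "ctype": state.ctype[:n],
        "tvol": state.tvol[:n],
        "pol": state.pol[:n],
        "parent": state.parent[:n],
        "step": np.array(state.step),
        "cum_shift": state.cum_shift,
        "params": np.frombuffer(
            json.dumps(vars(state.params)).encode(), dtype=np.uint8),
    }
    for name, f in (fields or {}).items():
        payload[f"field_{name}"] = f.values if hasattr(f, "values") else f
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> tuple[TissueState, dict]:
    with np.load(path) as data:
        params = SimParams(**json.loads(bytes(data["params"]).decode()))
        state = TissueState(data["owner"], data["ctype"], tvol=data["tvol"],
                            params=params)
        state.pol[: state.n_ids] = data["pol"]
        state.parent[: state.n_ids] = data["parent"]
        state.step = int(data["step"])
        state.cum_shift = data["cum_shift"].copy()
        fields = {k[len("field_"):]: data[k].copy()
                  for k in data.files if k.startswith("field_")}
    return state, fields
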