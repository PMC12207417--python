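"""Scikit-learn style segmenter estimators.

Two interchangeable pixel classifiers over grayscale echograms:

* :class:`UNetSegmenter` — the trainable U-Net. ``fit(X, y)`` takes stacks
  of grayscale images and integer class masks, trains with Adam on weighted
  cross-entropy, and keeps the epoch checkpoint with the best validation
  loss. ``predict_proba`` tiles arbitrarily-sized echograms, averaging
  probabilities on tile overlaps; ``predict`` applies per-class decision
  thresholds.
* :class:`ReferenceSegmenter` — a deterministic rule-based segmenter
  (threshold, connected components, shape/intensity rules) used as an
  independent oracle for the downstream pipeline and for low-noise data.

Both expose ``get_params``/``set_params`` and compose with sklearn tooling.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from ..classes import (
    BACKGROUND,
    BUBBLE_TRAIL,
    CLASS_PRECEDENCE,
    DEFAULT_CLASS_WEIGHTS,
    KRILL_SWARM,
    N_CLASSES,
    SEAFLOOR,
    WHALE,
)
from ..preprocess import grayscale_to_sv_array
from .unet import NumpyUNet, UNetConfig, parameter_count, softmax

logger = logging.getLogger(__name__)

#: Class priority for exactly-tied probabilities: rarest class wins
#: (whale > bubble_trail > krill_swarm > seafloor > background).
_TIE_ORDER = tuple(reversed(CLASS_PRECEDENCE))


def _as_image(echogram) -> np.ndarray:
    """Accept Echogram objects or bare 2D arrays."""
    if isinstance(echogram, np.ndarray):
        return echogram
    if hasattr(echogram, "units"):  # Echogram dataclass
        return echogram.data
    return np.asarray(echogram)


def _tile_starts(dim: int, tile: int) -> np.ndarray:
    """Tile start offsets covering [0, dim) with a final edge-aligned tile."""
    if dim < tile:
        raise ValueError(f"tile size {tile} exceeds image dimension {dim}")
    if dim == tile:
        return np.array([0])
    stride = max(1, int(np.ceil((dim - tile) / np.ceil((dim - tile) / tile))))
    starts = list(range(0, dim - tile, stride)) + [dim - tile]
    return np.unique(starts)


def threshold_labels(probs: np.ndarray, thresholds) -> np.ndarray:
    """Per-pixel label: the highest-probability class among those meeting
    their threshold; background if none does. Exact ties resolve by class
    priority (whale > bubble_trail > krill_swarm > seafloor > background).
    With all thresholds 0 this degenerates to argmax labeling."""
    thr = np.asarray(thresholds, dtype=probs.dtype)
    if thr.shape != (probs.shape[-1],):
        raise ValueError("thresholds must give one value per class")
    score = np.where(probs >= thr, probs, -np.inf)
    order = np.array(_TIE_ORDER)
    labels = order[np.argmax(score[..., order], axis=-1)]
    none_pass = ~np.isfinite(score).any(axis=-1)
    labels = labels.astype(np.int8)
    labels[none_pass] = BACKGROUND
    return labels


class UNetSegmenter(BaseEstimator):
    """Five-class echogram segmenter backed by the NumPy U-Net.

    Parameters mirror :class:`~divetrace.segmentation.unet.UNetConfig`;
    fitted attributes carry the trained network (``model_``), per-epoch
    losses (``history_``), the selected checkpoint epoch (``best_epoch_``)
    and the trainable parameter count (``n_parameters_``).
    """

    def __init__(
        self,
        levels: int = 4,
        base_filters: int = 16,
        bridge_width: int | None = None,
        n_classes: int = N_CLASSES,
        tile_size: int = 256,
        class_weights: tuple = DEFAULT_CLASS_WEIGHTS,
        epochs: int = 100,
        batch_size: int = 20,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.levels = levels
        self.base_filters = base_filters
        self.bridge_width = bridge_width
        self.n_classes = n_classes
        self.tile_size = tile_size
        self.class_weights = class_weights
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    def _config(self) -> UNetConfig:
        return UNetConfig(
            levels=self.levels,
            base_filters=self.base_filters,
            bridge_width=self.bridge_width,
            n_classes=self.n_classes,
            tile_size=self.tile_size,
            class_weights=tuple(self.class_weights),
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )

    def build(self) -> "UNetSegmenter":
        """Instantiate the (untrained) network and report its size."""
        cfg = self._config()
        self.model_ = NumpyUNet(cfg)
        self.n_parameters_ = self.model_.n_parameters
        assert self.n_parameters_ == parameter_count(cfg)
        logger.info("U-Net built: %d trainable parameters", self.n_parameters_)
        return self

    @classmethod
    def from_config(cls, cfg: UNetConfig) -> "UNetSegmenter":
        return cls(
            levels=cfg.levels,
            base_filters=cfg.base_filters,
            bridge_width=cfg.bridge_width,
            n_classes=cfg.n_classes,
            tile_size=cfg.tile_size,
            class_weights=cfg.class_weights,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            random_state=cfg.seed,
        )

    # -- training ---------------------------------------------------------

    @staticmethod
    def _stack(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        imgs = np.stack([_as_image(im) for im in X]).astype(np.float32)
        masks = np.stack([np.asarray(m) for m in y]).astype(np.int64)
        valid = np.isfinite(imgs)
        imgs = np.nan_to_num(imgs, nan=0.0)
        return imgs, masks, valid.astype(np.float32)

    def fit(self, X, y, validation_data=None):
        """Train on (images, masks); keep the best-validation-loss epoch.

        ``X``/``y`` are sequences of equally-sized grayscale images and
        integer masks (NaN pixels in X are excluded from the loss). When
        ``validation_data=(Xv, yv)`` is absent the training loss selects
        the checkpoint instead.
        """
        if len(X) == 0:
            raise ValueError("training set is empty")
        if not hasattr(self, "model_"):
            self.build()
        xb, yb, vb = self._stack(X, y)
        # Initialize the output bias at the log class priors: the network
        # then starts from the marginal label distribution instead of
        # spending its first epochs learning it against imbalanced classes.
        freq = np.bincount(yb.ravel(), minlength=self.n_classes).astype(np.float64)
        freq = np.maximum(freq, 1.0) / freq.sum()
        self.model_.params["out_b"] = np.log(freq).astype(np.float32)
        if validation_data is not None:
            xv, yv, vv = self._stack(*validation_data)
        rng = np.random.default_rng(self.random_state)
        n = xb.shape[0]
        bs = self.batch_size
        history = {"train_loss": [], "val_loss": []}
        best_loss, best_state, best_epoch = np.inf, None, -1
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, bs):
                sel = order[lo:lo + bs]
                losses.append(self.model_.train_step(xb[sel], yb[sel], vb[sel]))
            train_loss = float(np.mean(losses))
            history["train_loss"].append(train_loss)
            if validation_data is not None:
                val_loss = float(self.model_.evaluate_loss(xv, yv, vv))
            else:
                val_loss = train_loss
            history["val_loss"].append(val_loss)
            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_state = self.model_.state_dict()
            logger.info(
                "epoch %d/%d train %.4f val %.4f", epoch + 1, self.epochs,
                train_loss, val_loss,
            )
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        return self

    # -- checkpoint io ----------------------------------------------------

    def save(self, path) -> None:
        """Serialize hyperparameters + trained weights to one .npz file."""
        import json

        payload = dict(self.model_.params)
        payload["_params_json"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        import json

        with np.load(path) as data:
            params = json.loads(bytes(data["_params_json"].tobytes()).decode())
            if isinstance(params.get("class_weights"), list):
                params["class_weights"] = tuple(params["class_weights"])
            seg = cls(**params).build()
            seg.model_.load_state_dict(
                {k: data[k] for k in data.files if k != "_params_json"}
            )
        return seg

    # -- inference --------------------------------------------------------

    def predict_proba_image(self, echogram) -> np.ndarray:
        """Class probabilities (H, W, K) for one echogram of any size >=
        tile_size, tiling with overlap and averaging overlapping tiles."""
        img = _as_image(echogram).astype(np.float32)
        valid = np.isfinite(img)
        img = np.nan_to_num(img, nan=0.0)
        H, W = img.shape
        T = self.tile_size
        acc = np.zeros((H, W, self.n_classes), dtype=np.float32)
        cnt = np.zeros((H, W, 1), dtype=np.float32)
        r_starts = _tile_starts(H, T)
        c_starts = _tile_starts(W, T)
        tiles = [
            img[r:r + T, c:c + T] for r in r_starts for c in c_starts
        ]
        probs = self.model_.predict_proba(np.stack(tiles))
        k = 0
        for r in r_starts:
            for c in c_starts:
                acc[r:r + T, c:c + T] += probs[k]
                cnt[r:r + T, c:c + T] += 1.0
                k += 1
        out = acc / cnt
        # padding pixels carry no information: force certain background
        out[~valid] = 0.0
        out[~valid, BACKGROUND] = 1.0
        return out

    def predict_proba(self, X) -> np.ndarray:
        return np.stack([self.predict_proba_image(im) for im in X])

    def predict_image(self, echogram, thresholds=None) -> np.ndarray:
        probs = self.predict_proba_image(echogram)
        thr = np.zeros(self.n_classes) if thresholds is None else thresholds
        labels = threshold_labels(probs, thr)
        labels[~np.isfinite(_as_image(echogram))] = BACKGROUND
        return labels

    def predict(self, X, thresholds=None) -> np.ndarray:
        return np.stack([self.predict_image(im, thresholds) for im in X])


def predict_and_threshold(model: UNetSegmenter, echogram, thresholds):
    """(ProbabilityMap, SegmentationMask) for one echogram: tiled U-Net
    probabilities, then per-class threshold labeling with padding forced to
    background."""
    probs = model.predict_proba_image(echogram)
    labels = threshold_labels(probs, thresholds)
    labels[~np.isfinite(_as_image(echogram))] = BACKGROUND
    return probs, labels


class ReferenceSegmenter(BaseEstimator):
    """Deterministic rule-based five-class segmenter.

    Pixels above an Sv threshold are grouped into 8-connected components
    and classified by shape and intensity:

    * a near-full-width band in the lower half of the image -> seafloor;
    * per-column vertical extent <= ~2 m with net ascent -> bubble trail;
    * vertical extent >= 3 m with high mean Sv -> whale;
    * anything else -> krill swarm.

    Intended as the independent oracle for noise-free synthetic scenes and
    as a no-training fallback segmenter; it has no fit step.
    """

    def __init__(
        self,
        threshold_db: float = -72.0,
        bubble_max_col_px: int = 4,
        whale_min_rows: int = 6,
        whale_min_db: float = -55.0,
        seafloor_min_width_frac: float = 0.8,
        min_pixels: int = 3,
    ):
        self.threshold_db = threshold_db
        self.bubble_max_col_px = bubble_max_col_px
        self.whale_min_rows = whale_min_rows
        self.whale_min_db = whale_min_db
        self.seafloor_min_width_frac = seafloor_min_width_frac
        self.min_pixels = min_pixels

    def fit(self, X=None, y=None):
        return self

    def _classify_component(self, rows, cols, mean_db, n_rows, n_cols) -> int:
        width = cols.max() - cols.min() + 1
        height = rows.max() - rows.min() + 1
        if (
            width >= self.seafloor_min_width_frac * n_cols
            and rows.min() > 0.5 * n_rows
        ):
            return SEAFLOOR
        # per-column vertical extent
        rel = cols - cols.min()
        col_top = np.full(width, np.inf)
        col_bot = np.full(width, -np.inf)
        np.minimum.at(col_top, rel, rows)
        np.maximum.at(col_bot, rel, rows)
        occupied = np.isfinite(col_top)
        col_extent = (col_bot - col_top + 1)[occupied]
        if col_extent.max() <= self.bubble_max_col_px and width >= 5:
            centers = ((col_top + col_bot) / 2.0)[occupied]
            if centers.size >= 2 and centers[-1] <= centers[0]:
                return BUBBLE_TRAIL
        if height >= self.whale_min_rows and mean_db >= self.whale_min_db:
            return WHALE
        return KRILL_SWARM

    def predict_image(self, echogram) -> np.ndarray:
        img = _as_image(echogram)
        sv = grayscale_to_sv_array(img) if np.nanmax(img, initial=0.0) <= 1.0 else img
        binary = np.isfinite(sv) & (sv >= self.threshold_db)
        labels = measure.label(binary, connectivity=2)
        out = np.full(img.shape, BACKGROUND, dtype=np.int8)
        n_rows, n_cols = img.shape
        for comp in measure.regionprops(labels):
            if comp.area < self.min_pixels:
                continue
            rows, cols = comp.coords[:, 0], comp.coords[:, 1]
            mean_db = float(sv[rows, cols].mean())
            out[rows, cols] = self._classify_component(
                rows, cols, mean_db, n_rows, n_cols
            )
        return out

    def predict(self, X) -> np.ndarray:
        return np.stack([self.predict_image(im) for im in X])


def reference_segmenter(echogram, **params) -> np.ndarray:
    """Functional wrapper over :class:`ReferenceSegmenter`."""
    return ReferenceSegmenter(**params).predict_image(echogram)


def reduced_segmenter(random_state: int = 0) -> UNetSegmenter:
    """The package's reduced training-scale configuration: a 2-level
    U-Net on 64-px tiles, 15 epochs, batch 20. Small enough to train on
    one CPU in a couple of minutes while still learning all five classes
    of the synthetic corpus."""
    return UNetSegmenter(
        levels=2,
        base_filters=8,
        tile_size=64,
        epochs=15,
        batch_size=20,
        learning_rate=2e-3,
        random_state=random_state,
    )


def build_segmenter(config: UNetConfig) -> UNetSegmenter:
    """Untrained model handle from a config; parameter count is computed
    and logged."""
    return UNetSegmenter.from_config(config).build()
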