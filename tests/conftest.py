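import numpy as np
import pytest

from anodet.data_io import LABEL_NORMAL, LABEL_NOT_NORMAL, LABEL_OPACITY, Manifest, ImageRecord
from anodet.networks import NetworkConfig
from anodet.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net_config():
    return NetworkConfig(max_resolution=8)


def make_manifest(n_normal, n_opacity=0, n_not_normal=0, resolution=8):
    """Metadata-only manifest with deterministic ids, for split tests."""
    records = []
    i = 0
    for label, count in ((LABEL_NORMAL, n_normal), (LABEL_OPACITY, n_opacity),
                         (LABEL_NOT_NORMAL, n_not_normal)):
        for _ in range(count):
            records.append(ImageRecord(id=f"r{i:06d}", pixels=None, label=label,
                                       metadata={"resolution": resolution}))
            i += 1
    return Manifest(records)


class StubModel:
    """Duck-typed model whose four networks are fixed simple functions.

    encode: configurable map (default zeros); generate: configurable
    (default: return the last encoded batch, i.e. a perfect autoencoder when
    composed); critics return constant logits.
    """

    def __init__(self, latent_dim=128, resolution=4, encode_fn=None,
                 generate_fn=None, disc_logit=0.0, code_logit=0.0):
        self.latent_dim = latent_dim
        self.current_resolution = resolution
        self.fade_alpha = 1.0
        self._last_batch = None
        self._encode_fn = encode_fn
        self._generate_fn = generate_fn
        self._disc_logit = disc_logit
        self._code_logit = code_logit

    def encode(self, x: Tensor) -> Tensor:
        self._last_batch = x
        if self._encode_fn is not None:
            return self._encode_fn(x)
        return Tensor(np.zeros((x.shape[0], self.latent_dim), dtype=np.float64))

    def generate(self, z: Tensor) -> Tensor:
        if self._generate_fn is not None:
            return self._generate_fn(z)
        return Tensor(self._last_batch.data.copy())  # perfect reconstruction

    def discriminate(self, x: Tensor) -> Tensor:
        return Tensor(np.full((x.shape[0], 1), self._disc_logit))

    def discriminate_code(self, z: Tensor) -> Tensor:
        return Tensor(np.full((z.shape[0], 1), self._code_logit))

    def encode_images(self, images):
        arr = np.asarray(images)
        if arr.ndim == 2:
            arr = arr[None]
        return self.encode(Tensor(arr[:, None])).data

    def reconstruct_images(self, images):
        arr = np.asarray(images)
        if arr.ndim == 2:
            arr = arr[None]
        x = Tensor(arr[:, None])
        return self.generate(self.encode(x)).data[:, 0]
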