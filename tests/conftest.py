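"""Shared fixtures.

The default synthetic scene plus its embeddings are expensive (1,500 voxels,
1,200 timepoints, two diffusion maps), so they are computed once per session
and shared across the parcellation, clustering, and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from conngrad import connectome, embed, synth

SCENE_SEED = 0
RECOVERY_NOISE_SD = 0.25  # the noise level at which latent recovery is asserted
N_TARGETS = 400


def latent_reference(scene) -> embed.GradientSet:
    """The scene's latent coordinates wrapped as a 2-component gradient set."""
    return embed.GradientSet(
        np.column_stack([scene.latent.latent_g1, scene.latent.latent_g2]),
        np.array([1.0, 1.0]),
        scene.latent.voxel_ids,
        params={"source": "latent ground truth"},
    )


def embed_connectome(conn, keep_pct: float = 10.0, n_components: int = 8):
    aff = embed.cosine_affinity(embed.sparsify_rows(conn, keep_pct))
    return embed.diffusion_map(aff, n_components=n_components)


@pytest.fixture(scope="session")
def default_scene():
    """Default scene at the recovery noise level, with a cortical target set."""
    return synth.make_scene(
        noise_sd=RECOVERY_NOISE_SD, seed=SCENE_SEED, n_targets=N_TARGETS
    )


@pytest.fixture(scope="session")
def scene_gradients(default_scene):
    """Intra-set gradients of the default scene, matched to the latent axes."""
    scene = default_scene
    ts = connectome.TimeseriesMatrix(scene.timeseries, scene.latent.voxel_ids)
    conn = connectome.correlation_connectome(ts)
    g = embed_connectome(conn)
    return embed.match_gradients(g, latent_reference(scene), 2)


@pytest.fixture(scope="session")
def settotarget_gradients(default_scene, scene_gradients):
    """Gradients from the rectangular (set-to-target) connectome, matched to
    the intra-set gradients."""
    scene = default_scene
    ts = connectome.TimeseriesMatrix(scene.timeseries, scene.latent.voxel_ids)
    tts = connectome.TimeseriesMatrix(
        scene.target_timeseries, scene.target_latent.voxel_ids
    )
    rect = connectome.correlation_connectome(ts, tts)
    g = embed_connectome(rect)
    return embed.match_gradients(g, scene_gradients, 2)
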