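"""Shared test settings.

The phantom renders filaments as 10 nm-radius solid cylinders, so the
correlation template used across the tests is matched to that radius
(defaults elsewhere keep the production template). Phantom filaments are
near-axial, so orientation sampling is coarsened and restricted to a
30-degree cone around the longitudinal axis to keep the FFT correlation
passes cheap.
"""

MATCHED_TEMPLATE = dict(outer_radius_nm=10.0, mask_radius_nm=20.0,
                        angular_sampling_deg=15.0)
MAX_TILT_DEG = 30.0
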