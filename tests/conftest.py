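from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")
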