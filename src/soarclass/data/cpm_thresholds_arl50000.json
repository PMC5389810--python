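{"arl0": 50000.0, "min_side": 5, "k_cap": 256, "method": "tail-extrapolated", "t": [10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50, 52, 54, 56, 58, 60, 62, 68, 74, 81, 88, 97, 106, 115, 126, 138, 150, 164, 180, 196, 215, 234, 256, 280, 306, 334, 365, 399, 436, 476, 521, 569, 622, 679, 742, 811, 886, 968, 1058, 1156, 1263, 1380, 1508, 1648, 1801, 1968, 2150, 2350, 2568, 2806, 3066, 3350, 3661, 4000], "h": [30.8025, 31.2192, 31.9825, 33.0434, 33.4352, 33.3572, 33.8361, 33.6071, 33.7162, 33.6348, 33.7519, 33.4286, 32.9135, 32.5586, 32.3486, 32.0919, 32.3927, 33.1444, 33.3418, 33.8267, 34.7203, 35.01, 34.6168, 34.6693, 34.6778, 33.9426, 32.921, 32.4489, 32.2299, 31.5458, 31.1323, 31.3646, 31.4772, 31.2076, 31.4603, 31.8215, 31.6364, 31.9033, 32.5968, 32.5029, 32.4455, 32.7557, 32.6079, 32.0368, 32.0219, 31.9029, 31.7855, 31.87, 31.9148, 31.9746, 31.8538, 31.9552, 31.5803, 31.424, 31.1839, 31.0954, 30.6549, 30.8461, 31.0016, 30.7442, 30.7191, 30.9193, 30.774, 30.6939, 31.0333, 30.8952, 30.6265, 30.246, 29.6718, 29.3847, 29.4371, 28.9437, 28.9842, 29.1778], "meta": {"reps": 6000, "horizon": 4000, "seed": 20170412}}
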