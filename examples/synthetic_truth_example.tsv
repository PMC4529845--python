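subject_id	side	true_theta_a	true_theta_c	true_ridge_angle
S01	right	60.07053791563121	14.276178307530925	44.85337521068385
S01	left	52.24695181898888	21.10638208906782	47.191380713823925
S02	right	56.71558610546808	15.418396454610962	51.27874615549103
S02	left	58.07672521758766	10.606136233026117	50.18571386921993
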