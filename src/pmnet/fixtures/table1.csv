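sensor,n_pre,r2_pre,rmse_pre,slope_pre,intercept_pre,n_post,r2_post,rmse_post,slope_post,intercept_post,slope_avg,intercept_avg
13th Ave,47,0.99,0.38,0.91,0.03,470,0.99,0.69,0.96,-0.19,0.94,-0.08
24th Ave,47,0.99,0.47,0.93,-0.53,469,0.99,0.70,0.96,-0.49,0.94,-0.51
64th St,152,0.99,0.92,1.01,0.93,467,0.99,0.53,1.06,0.09,1.03,0.51
ARB T St 2,146,0.99,1.61,0.81,-0.15,467,0.99,1.02,0.75,0.07,0.78,-0.04
ARB T St 3,150,0.99,1.11,0.95,1.19,467,0.99,0.26,1.02,0.15,0.98,0.67
Alderwood,150,0.99,1.23,0.88,1.51,465,0.99,0.34,0.95,0.09,0.92,0.80
Coroval,138,0.99,0.92,1.15,0.16,378,0.99,0.58,1.26,-0.70,1.20,-0.27
Del Paso 2,152,0.99,1.51,0.80,2.64,465,0.99,1.09,0.87,1.37,0.83,2.00
Del Paso 3,152,0.99,0.81,1.10,-0.53,468,0.99,0.59,1.19,-0.78,1.15,-0.66
Darwin St,88,0.99,0.82,0.99,0.55,466,0.99,0.36,1.04,-0.22,1.01,0.16
Henrietta Dr,47,0.99,0.60,1.55,-1.17,291,0.99,0.59,1.73,-0.51,1.64,-0.84
Socorro Way,88,0.99,0.88,0.96,0.74,464,0.99,0.42,1.00,-0.22,0.98,0.26
Tristan Cir,138,0.98,2.55,0.97,-2.95,466,0.98,1.52,0.94,-1.00,0.95,-1.98
Wyman,47,0.99,0.88,1.10,1.17,467,0.99,1.14,1.07,1.24,1.08,1.21
79th St,62,0.99,0.69,0.93,-0.39,466,0.99,0.65,0.84,-0.71,0.89,-0.55
ARB T St,146,0.99,0.87,1.13,-1.67,392,0.99,0.43,1.06,-0.34,1.10,-1.01
Del Paso,152,0.99,1.17,1.13,0.09,150,0.99,0.43,1.06,0.44,1.13,0.09
Hermosa St,47,0.99,0.74,0.85,-0.30,291,0.99,0.55,0.83,-0.16,0.85,-0.30
T St Tier 3,152,0.98,2.45,1.08,-3.20,291,0.99,0.49,0.97,-0.30,1.08,-3.20
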