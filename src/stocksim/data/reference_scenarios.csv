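model,q_ldm_grp1,q_slr_grp1,q_src_grp1,q_ldm_grp2,q_slr_grp2,q_src_grp2,q_ldm_grp3,q_slr_grp3,q_src_grp3,fst_slr_ldm,fst_slr_src,fst_ldm_src,polym,rmse
empirical,0.101,0.033,0.978,0.881,0.102,0.020,0.018,0.865,0.002,0.036,0.23,0.178,3619,
m23_N600_D50,0.070,0.037,1.000,0.916,0.077,0.000,0.015,0.887,0.000,0.012,0.206,0.293,3619,0.05
m21_N600_D200,0.112,0.068,1.000,0.863,0.066,0.000,0.026,0.866,0.000,0.012,0.197,0.293,3621,0.57
m23_N600_D400,0.063,0.034,0.989,0.904,0.096,0.011,0.032,0.870,0.000,0.012,0.209,0.297,3616,0.94
m23_N600_D300,0.057,0.035,1.000,0.929,0.088,0.000,0.013,0.877,0.000,0.013,0.206,0.296,3615,1.16
m21_N600_D300,0.116,0.073,1.000,0.875,0.070,0.000,0.010,0.858,0.000,0.012,0.193,0.286,3615,1.21
m21_N600_D400,0.106,0.082,1.000,0.866,0.067,0.000,0.028,0.852,0.000,0.012,0.192,0.285,3624,1.38
m09_N600_D0,0.116,0.074,1.000,0.867,0.098,0.000,0.017,0.828,0.000,0.011,0.194,0.285,3625,1.60
m22_N600_D200,0.069,0.051,1.000,0.918,0.036,0.000,0.013,0.914,0.000,0.013,0.202,0.292,3629,2.87
m22_N600_D400,0.076,0.053,1.000,0.910,0.049,0.000,0.012,0.898,0.000,0.012,0.203,0.295,3630,2.92
m20_N600_D300,0.057,0.036,0.949,0.797,0.140,0.051,0.146,0.824,0.000,0.005,0.212,0.286,3604,4.17
m10_N600_D0,0.087,0.048,0.968,0.844,0.118,0.031,0.068,0.833,0.001,0.013,0.200,0.294,3638,5.20
m21_N600_D50,0.137,0.070,1.000,0.853,0.106,0.000,0.011,0.824,0.000,0.012,0.192,0.286,3641,5.97
m11_N600_D0,0.058,0.041,0.989,0.905,0.033,0.011,0.037,0.926,0.000,0.013,0.206,0.297,3597,6.17
m02_N600_D0,0.000,0.000,0.866,0.712,0.067,0.134,0.288,0.933,0.000,0.007,0.227,0.297,3596,6.32
m22_N600_D300,0.073,0.047,1.000,0.911,0.064,0.000,0.016,0.888,0.000,0.013,0.203,0.297,3596,6.38
m04_N600_D0,0.027,0.015,0.947,0.802,0.075,0.053,0.170,0.909,0.000,0.005,0.216,0.288,3594,7.01
m17_N600_D0,0.034,0.020,0.946,0.762,0.112,0.054,0.204,0.868,0.000,0.006,0.218,0.291,3592,7.50
m22_N600_D100,0.078,0.046,1.000,0.875,0.032,0.000,0.047,0.921,0.000,0.012,0.203,0.294,3647,7.79
m23_N600_D200,0.066,0.038,1.000,0.923,0.054,0.000,0.011,0.908,0.000,0.014,0.208,0.298,3650,8.59
m22_N600_D50,0.075,0.050,1.000,0.913,0.052,0.000,0.011,0.898,0.000,0.013,0.201,0.290,3654,9.70
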