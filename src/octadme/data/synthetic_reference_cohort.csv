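eye_id,patient_id,diabetes_type,hba1c,bcva_baseline,bcva_final,cmt_baseline,cmt_final,vma,macular_cysts,subretinal_fluid,hard_exudates,ez_alteration,macular_cysts_m12,subretinal_fluid_m12,hard_exudates_m12,ez_alteration_m12,microaneurysms,irma,neovascularization,vpd_scp,vpd_dcp,lac_scp,lac_dcp,vpd_scp_m12,vpd_dcp_m12,lac_scp_m12,lac_dcp_m12,n_injections
E001,P001,1,5.7,69,65,434.1,309.1,0,1,1,1,1,1,1,0,0,0,0,1,0.26,0.297,0.152,0.513,0.449,0.417,0.407,0.234,9
E002,P002,1,7.0,71,73,498.0,386.7,0,1,0,0,1,0,0,0,0,1,0,0,0.425,0.406,0.435,0.382,0.365,0.357,0.442,0.176,3
E003,P003,1,7.3,72,78,327.9,359.3,0,1,0,0,1,0,0,0,0,0,1,0,0.455,0.324,0.406,0.227,0.464,0.345,0.438,0.374,7
E004,P004,1,9.8,57,78,280.5,269.6,0,1,0,0,0,0,0,0,0,0,1,0,0.385,0.443,0.523,0.26,0.321,0.369,0.274,0.247,7
E005,P005,1,6.9,59,73,377.8,339.4,0,1,0,0,1,0,0,0,1,1,1,0,0.286,0.415,0.099,0.36,0.413,0.327,0.373,0.428,7
E006,P006,1,8.4,60,73,403.4,270.5,0,1,0,0,1,1,0,0,1,1,0,0,0.34,0.439,0.167,0.392,0.264,0.366,0.342,0.345,4
E007,P007,1,9.1,92,78,281.7,260.4,0,1,1,0,0,0,0,0,0,0,0,1,0.411,0.247,0.661,0.381,0.398,0.268,0.402,0.53,4
E008,P008,1,8.8,57,73,452.8,486.2,0,1,0,1,0,0,0,1,0,1,1,0,0.307,0.3,0.156,0.138,0.45,0.347,0.489,0.333,3
E009,P009,1,7.8,67,78,369.5,342.0,0,1,0,0,0,0,0,0,0,1,1,0,0.457,0.488,0.752,0.353,0.352,0.357,0.331,0.266,7
E010,P010,1,10.0,56,78,255.0,195.9,0,1,1,0,0,0,0,0,0,0,1,1,0.275,0.453,0.41,0.305,0.438,0.383,0.371,0.438,5
E011,P011,1,8.2,63,78,309.6,248.0,0,1,0,0,0,0,0,0,0,0,0,0,0.339,0.324,0.607,0.184,0.373,0.477,0.372,0.545,10
E012,P012,1,7.9,75,73,479.3,518.9,0,1,0,0,1,1,0,0,1,1,1,1,0.279,0.425,0.627,0.203,0.361,0.414,0.306,0.559,8
E013,P013,1,6.9,52,65,552.6,422.1,0,1,0,1,0,0,0,0,0,0,1,1,0.337,0.341,0.333,0.54,0.462,0.308,0.41,0.376,8
E014,P014,1,8.2,58,78,308.0,284.3,0,0,0,0,1,0,0,0,0,0,1,0,0.304,0.317,0.628,0.299,0.382,0.297,0.388,0.409,11
E015,P015,1,7.5,51,78,257.2,222.1,0,1,0,0,1,1,0,0,1,1,1,0,0.322,0.377,0.223,0.283,0.382,0.292,0.323,0.367,5
E016,P016,1,9.0,67,73,547.1,399.6,0,1,0,1,0,0,0,0,0,1,1,1,0.389,0.236,0.214,0.203,0.34,0.427,0.398,0.65,7
E017,P017,1,8.2,52,78,223.0,160.0,0,1,0,0,0,0,0,0,0,1,1,1,0.332,0.366,0.188,0.324,0.313,0.547,0.423,0.516,7
E018,P018,1,7.7,51,78,309.7,241.9,0,1,0,0,0,0,0,0,0,1,0,1,0.344,0.367,0.475,0.253,0.431,0.4,0.373,0.463,7
E019,P019,1,7.1,55,78,260.6,273.3,0,1,1,1,1,1,0,0,1,1,0,0,0.451,0.366,0.489,0.361,0.372,0.337,0.485,0.694,9
E020,P020,1,6.4,76,73,493.2,498.2,0,1,0,0,1,0,0,0,1,1,0,0,0.456,0.291,0.678,0.373,0.396,0.38,0.274,0.343,3
E021,P021,1,7.7,83,78,371.3,349.2,0,1,0,0,1,1,0,0,1,0,1,1,0.368,0.33,0.415,0.231,0.304,0.437,0.398,0.547,5
E022,P022,1,7.8,65,73,425.5,246.0,0,1,0,0,1,1,0,0,0,0,0,0,0.316,0.343,0.177,0.301,0.47,0.349,0.287,0.327,3
E023,P023,1,7.9,62,78,286.4,160.0,0,1,0,0,1,0,0,0,1,1,0,1,0.267,0.292,0.554,0.37,0.402,0.375,0.385,0.473,8
E024,P024,1,9.0,83,78,310.0,264.0,0,1,0,0,1,1,0,0,1,1,1,0,0.362,0.323,0.577,0.327,0.334,0.441,0.372,0.341,12
E025,P025,1,8.2,72,78,205.0,160.0,0,1,1,0,0,0,1,0,0,1,1,0,0.324,0.461,0.57,0.359,0.421,0.45,0.463,0.356,3
E026,P026,1,8.8,78,65,523.9,526.6,0,1,0,1,1,1,0,0,0,1,1,1,0.278,0.365,0.1,0.575,0.35,0.347,0.426,0.531,6
E027,P027,1,6.9,61,78,372.8,359.4,0,1,0,0,1,0,0,0,1,1,1,1,0.358,0.359,0.345,0.274,0.363,0.29,0.425,0.177,4
E028,P028,2,7.9,62,78,306.8,219.8,0,1,0,0,1,1,0,0,0,1,1,0,0.31,0.394,0.658,0.158,0.438,0.442,0.283,0.392,6
E029,P029,2,7.4,82,78,340.2,308.7,0,1,1,0,1,1,0,0,1,1,1,1,0.264,0.413,0.245,0.23,0.37,0.349,0.453,0.435,8
E030,P030,2,7.5,66,73,618.1,555.4,0,1,0,0,1,1,0,0,1,0,1,0,0.448,0.357,0.405,0.331,0.496,0.285,0.332,0.345,9
E031,P031,2,7.4,75,65,429.6,512.6,0,1,0,0,0,1,0,0,0,1,1,0,0.431,0.398,0.21,0.598,0.359,0.318,0.329,0.278,10
E032,P032,2,7.8,68,65,530.9,535.1,0,1,1,1,0,0,0,1,0,0,1,0,0.393,0.336,0.295,0.712,0.254,0.302,0.292,0.768,3
E033,P033,2,6.0,49,78,314.0,296.1,0,1,0,0,1,1,0,0,1,1,1,0,0.359,0.271,0.566,0.289,0.318,0.339,0.404,0.429,11
E034,P034,2,8.2,67,73,435.3,326.9,0,1,0,1,1,0,0,0,1,1,0,1,0.4,0.27,0.165,0.272,0.349,0.319,0.371,0.46,3
E035,P035,2,6.3,70,78,203.6,238.7,0,1,0,0,1,1,0,0,1,0,1,0,0.35,0.404,0.071,0.186,0.396,0.337,0.323,0.621,9
E036,P036,2,6.8,88,78,318.9,219.6,0,1,0,1,1,1,0,0,1,1,0,0,0.263,0.249,0.41,0.362,0.298,0.436,0.359,0.433,7
E037,P037,2,7.1,61,73,510.4,526.7,0,0,0,1,1,0,0,1,1,1,1,0,0.387,0.4,0.75,0.399,0.336,0.418,0.279,0.561,10
E038,P038,2,6.4,67,73,504.7,459.9,0,1,0,0,1,0,0,0,1,1,1,1,0.394,0.347,0.781,0.321,0.334,0.454,0.362,0.687,5
E039,P039,2,7.4,69,78,297.7,204.4,0,1,0,0,1,0,0,0,0,1,1,1,0.321,0.296,0.585,0.336,0.494,0.396,0.348,0.364,5
E040,P040,2,9.4,57,78,265.3,228.1,0,1,0,1,1,0,0,0,0,0,1,0,0.41,0.3,0.425,0.364,0.337,0.416,0.427,0.472,4
E041,P041,2,7.4,68,73,550.0,520.6,0,1,0,0,1,1,0,0,0,1,1,0,0.34,0.403,0.252,0.325,0.392,0.336,0.486,0.209,7
E042,P042,2,7.8,86,65,464.5,383.2,0,1,0,0,1,1,0,0,1,1,1,0,0.316,0.508,0.707,0.615,0.357,0.482,0.347,0.404,10
E043,P043,2,7.2,54,78,273.6,215.1,0,1,1,0,0,1,1,0,0,1,0,0,0.312,0.35,0.142,0.293,0.44,0.378,0.327,0.624,3
E044,P044,2,8.2,73,73,581.1,470.6,0,1,0,0,1,1,0,0,1,1,1,0,0.355,0.329,0.396,0.39,0.312,0.3,0.372,0.396,8
E045,P045,2,8.6,68,73,626.9,460.0,0,1,0,1,0,1,0,1,0,1,1,1,0.381,0.375,0.173,0.378,0.404,0.367,0.44,0.32,4
E046,P046,2,7.4,68,73,398.1,251.9,0,1,1,0,1,0,0,0,0,1,1,1,0.292,0.234,0.429,0.328,0.411,0.291,0.345,0.564,10
E047,P047,2,9.1,51,78,271.7,196.5,0,1,1,0,1,0,1,0,1,1,1,0,0.34,0.414,0.591,0.302,0.48,0.485,0.41,0.647,3
E048,P048,2,8.7,60,65,567.6,521.3,0,1,0,0,1,0,0,0,1,1,0,0,0.419,0.346,0.643,0.519,0.384,0.434,0.346,0.139,3
E049,P049,2,9.3,70,73,427.1,426.4,0,1,1,1,0,0,0,0,0,1,1,0,0.509,0.225,0.319,0.28,0.3,0.334,0.338,0.406,3
E050,P050,2,7.8,82,73,376.4,328.7,0,1,0,1,0,1,0,1,0,1,1,1,0.352,0.321,0.63,0.235,0.37,0.381,0.28,0.429,5
E051,P051,2,8.4,85,73,436.4,414.7,0,1,1,1,1,1,0,1,1,1,1,0,0.34,0.32,0.57,0.374,0.278,0.454,0.334,0.438,8
E052,P052,2,6.1,74,65,377.4,328.1,0,1,1,0,0,0,0,0,0,1,1,0,0.285,0.465,0.438,0.441,0.352,0.502,0.389,0.523,7
E053,P053,2,6.9,72,78,361.1,340.9,0,1,0,1,1,1,0,1,1,1,1,0,0.295,0.364,0.789,0.374,0.357,0.351,0.463,0.31,3
E054,P054,2,7.9,60,65,449.7,370.2,0,1,0,1,1,1,0,1,0,1,1,0,0.474,0.275,0.634,0.526,0.519,0.374,0.377,0.469,6
E055,P055,2,7.6,65,73,579.6,597.4,0,1,0,1,1,0,0,1,0,1,1,0,0.397,0.24,0.642,0.221,0.421,0.346,0.357,0.519,8
E056,P056,2,7.4,83,73,478.2,270.3,0,1,0,0,1,1,0,0,0,1,0,1,0.365,0.521,0.73,0.271,0.442,0.485,0.339,0.317,4
E057,P057,2,8.4,84,78,267.2,232.7,0,1,1,0,0,0,0,0,0,1,1,0,0.444,0.414,0.244,0.309,0.407,0.452,0.327,0.064,4
E058,P058,2,7.5,53,73,502.4,391.0,0,1,0,0,1,1,0,0,0,0,1,0,0.258,0.437,0.122,0.229,0.404,0.449,0.347,0.23,6
E059,P059,2,8.6,92,65,680.8,643.4,0,1,1,0,0,1,0,0,0,0,1,0,0.385,0.409,0.211,0.584,0.234,0.44,0.38,0.741,7
E060,P060,2,6.9,51,78,353.1,200.0,0,1,0,1,1,1,0,0,1,1,1,1,0.346,0.488,0.393,0.333,0.425,0.357,0.372,0.413,6
E061,P061,2,7.2,78,73,503.3,470.1,0,1,0,1,1,0,0,0,1,1,1,0,0.319,0.553,0.494,0.289,0.448,0.43,0.387,0.396,8
E062,P062,2,5.8,50,78,299.8,161.4,0,1,0,0,0,0,0,0,0,1,1,0,0.308,0.328,0.748,0.326,0.356,0.376,0.389,0.137,7
E063,P059,2,6.5,70,78,368.7,393.0,0,1,1,1,1,0,0,0,0,0,0,0,0.391,0.375,0.229,0.316,0.398,0.39,0.461,0.452,5
E064,P060,2,9.1,62,73,529.2,573.4,0,0,0,0,1,0,0,0,1,1,0,0,0.404,0.44,0.431,0.373,0.354,0.53,0.372,0.398,9
E065,P061,2,7.8,74,73,467.7,334.2,0,1,0,1,1,1,0,0,1,0,1,0,0.358,0.348,0.414,0.342,0.335,0.381,0.313,0.417,3
E066,P062,2,8.8,54,73,457.6,364.2,0,1,0,0,1,1,0,0,1,1,1,1,0.218,0.341,0.544,0.253,0.417,0.388,0.32,0.072,6
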