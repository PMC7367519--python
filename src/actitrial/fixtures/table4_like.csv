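participant_id,arm,attended_education,calls_completed,wk1,wk2,wk3,wk4,wk5,wk6,wk7,wk8,wk9,wk10,wk11,wk12
A001,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A002,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A003,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A004,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A005,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A006,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A007,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A008,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A009,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A010,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A011,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A012,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A013,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A014,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A015,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A016,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A017,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A018,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A019,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A020,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A021,IG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A022,IG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A023,IG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A024,IG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A025,IG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A026,IG,1,2,7,7,7,7,7,7,7,7,7,7,4,3
A027,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A028,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A029,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A030,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A031,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A032,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A033,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A034,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A035,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A036,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A037,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A038,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A039,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A040,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A041,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A042,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A043,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A044,DG,1,4,7,7,7,7,7,7,7,7,7,7,7,7
A045,DG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A046,DG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A047,DG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A048,DG,1,3,7,7,7,7,7,7,7,7,7,7,4,3
A049,DG,1,1,7,7,7,7,7,7,7,7,7,7,7,7
A050,DG,1,1,7,7,7,7,7,7,7,7,7,7,7,7
A051,DG,1,2,7,7,7,7,7,7,7,7,7,7,4,3
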